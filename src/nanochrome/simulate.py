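"""Ground-truthed synthetic dark-field image generator.

Emulates the acquisition used for digital plasmonic counting: antibody/PEG
functionalised ~80 +/- 9 nm gold nanoparticles flow through a microfluidic
channel and are imaged in two spectral channels (G-band 545-552 nm, R-band
590-622 nm) by a color camera at high magnification.  Each particle appears
as a diffraction-limited Gaussian spot; a small fraction of particles are
doublet aggregates that appear as oversized spots.  Analyte (IL-6) binding
thickens the protein shell from 1.67 nm to 1.77 nm on bound particles,
red-shifting the LSPR and raising the R/G intensity ratio.

Noise and heterogeneity model (see docs/methods.md for the rationale):

* diameters ~ Normal(80, 9) truncated at +/-3 sd; diameter controls spot
  brightness (via the Mie cross-section) and, in aggregates, footprint;
* per-particle protein-shell thickness ~ Normal(base, shell_sd) truncated
  at 0: antibody-coverage heterogeneity, the dominant chromatic spread;
* binding follows a heterogeneous-affinity (Sips) isotherm
  p = c^h / (c^h + Kd^h);
* detection is shot-noise limited: per-pixel Poisson photon noise, camera
  gain (ADU per photon), Gaussian read noise, constant background.

By default the chromatic contrast gamma of a particle is evaluated at the
population-mean core diameter (diameter enters brightness only); set
``size_dependent_contrast=True`` for the full per-diameter Mie response.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .instrument import BandSet, NONADJACENT_BANDS, band_intensities
from .optics import OpticalConstants, ParticleModel, load_gold_constants, scattering_spectrum

__all__ = [
    "PopulationConfig",
    "BindingModel",
    "ImagingConfig",
    "BandResponseTable",
    "SimulatedDataset",
    "sample_particles",
    "bind_analyte",
    "render_frames",
    "generate_dataset",
    "write_dataset",
]


class ConfigurationError(ValueError):
    """Simulation configuration cannot be realised (e.g. spot packing)."""


@dataclass(frozen=True)
class PopulationConfig:
    """Particle population: geometry and optical make-up.

    mean_diameter/sd_diameter describe the gold core (nm); base_shell is the
    antibody+PEG layer thickness and bound_shell that layer plus the captured
    analyte (nm); shell_sd is the particle-to-particle spread of the protein
    layer (coverage heterogeneity); aggregate_fraction is the doublet rate.
    """

    mean_diameter: float = 80.0
    sd_diameter: float = 9.0
    aggregate_fraction: float = 0.02
    base_shell: float = 1.67
    bound_shell: float = 1.77
    shell_sd: float = 0.10
    shell_index: float = 1.45
    medium_index: float = 1.333
    size_dependent_contrast: bool = False

    def __post_init__(self):
        if self.sd_diameter < 0 or self.shell_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.aggregate_fraction <= 1:
            raise ValueError("aggregate_fraction must be in [0, 1]")
        if self.bound_shell < self.base_shell:
            raise ValueError("bound_shell must be >= base_shell")


@dataclass(frozen=True)
class BindingModel:
    """Per-particle occupancy p = c^h / (c^h + Kd^h) (Sips isotherm).

    Kd is in the assay's concentration units (pg/mL).  The fractional Hill
    exponent models the heterogeneous-affinity surface that gives the assay
    its log-linear dose response over the 100 fg/mL - 1 ng/mL range.
    """

    kd: float = 10.0
    hill: float = 0.2

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")

    def bound_probability(self, concentration: float) -> float:
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        if concentration == 0:
            return 0.0
        ch = concentration**self.hill
        return ch / (ch + self.kd**self.hill)


@dataclass(frozen=True)
class ImagingConfig:
    """Camera/optics parameters for frame rendering.

    photons_per_unit_cross_section scales band-integrated Mie intensity
    (nm^2 nm) to detected photons; the default gives ~4.5e6 photons per mean
    particle per 10 ms exposure, so the shot-noise contribution to the
    chromatic contrast (sigma_gamma ~ 5e-4) stays below the shell
    heterogeneity term.  adu_per_photon is the camera gain; background and
    read noise are in ADU.  Spots are placed uniformly at random with a
    minimum separation of min_separation_factor * psf_sigma (wide enough
    that no neighbour intrudes on a spot's background annulus) and an edge
    margin.
    """

    frame_shape: tuple[int, int] = (512, 512)
    psf_sigma: float = 2.2
    photons_per_unit_cross_section: float = 12.0
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    spots_per_frame: int = 150
    adu_per_photon: float = 0.1
    edge_margin: int = 16
    min_separation_factor: float = 6.0
    shot_noise: bool = True

    def __post_init__(self):
        if self.psf_sigma < 0.5:
            raise ValueError("psf_sigma must be >= 0.5 px")
        if min(self.frame_shape) <= 2 * self.edge_margin:
            raise ValueError("frame too small for the edge margin")
        for name in (
            "photons_per_unit_cross_section",
            "background_level",
            "adu_per_photon",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.spots_per_frame <= 0:
            raise ValueError("spots_per_frame must be > 0")


def sample_particles(n: int, pop: PopulationConfig, seed) -> pd.DataFrame:
    """Draw a particle table: core diameters (truncated normal, +/-3 sd),
    per-particle shell thickness around base_shell, aggregate flags, and a
    second core diameter for aggregate doublets."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    if pop.sd_diameter == 0:
        d = np.full(n, pop.mean_diameter)
        d2 = np.full(n, pop.mean_diameter)
    else:
        tn = stats.truncnorm(-3, 3, loc=pop.mean_diameter, scale=pop.sd_diameter)
        d = tn.rvs(size=n, random_state=rng)
        d2 = tn.rvs(size=n, random_state=rng)
    if pop.shell_sd == 0:
        shell = np.full(n, pop.base_shell)
    else:
        lo = -pop.base_shell / pop.shell_sd
        shell = stats.truncnorm(lo, np.inf, loc=pop.base_shell, scale=pop.shell_sd).rvs(
            size=n, random_state=rng
        )
    is_agg = rng.random(n) < pop.aggregate_fraction
    return pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "diameter": d,
            "diameter2": np.where(is_agg, d2, np.nan),
            "shell": shell,
            "is_aggregate": is_agg,
            "bound": np.zeros(n, dtype=bool),
        }
    )


def bind_analyte(
    particles: pd.DataFrame, concentration: float, model: BindingModel, seed
) -> pd.DataFrame:
    """Assign analyte occupancy: each particle binds with probability
    p(concentration); bound particles carry the thicker shell (the base
    shell plus the analyte layer increment)."""
    p = model.bound_probability(concentration)
    rng = np.random.default_rng(seed)
    out = particles.copy()
    bound = rng.random(len(out)) < p
    out["bound"] = bound
    return out


class BandResponseTable:
    """Precomputed Mie band intensities R(d, t), G(d, t) for fast lookup.

    Interpolates the band-integrated scattering intensities over core
    diameter and shell thickness; the simulator queries it once per
    particle.  With ``size_dependent_contrast`` False the chromatic ratio
    R/G is taken at the population-mean diameter and the diameter only
    rescales total brightness.
    """

    def __init__(
        self,
        pop: PopulationConfig,
        bands: BandSet = NONADJACENT_BANDS,
        constants: OpticalConstants | None = None,
        d_step: float = 1.0,
        t_max: float = 3.0,
        t_step: float = 0.1,
        band_step: float = 0.5,
    ):
        self.pop = pop
        self.bands = bands
        self.constants = constants or load_gold_constants()
        lo = bands.g_band[0] - 2.0
        hi = bands.r_band[1] + 2.0
        self._grid = np.arange(lo, hi + band_step / 2, band_step)
        d_lo = max(pop.mean_diameter - 3 * pop.sd_diameter - 2 * d_step, 5.0)
        d_hi = pop.mean_diameter + 3 * pop.sd_diameter + 2 * d_step
        self._d_grid = np.arange(d_lo, d_hi + d_step / 2, d_step)
        self._t_grid = np.arange(0.0, t_max + t_step / 2, t_step)
        # shell response at the mean diameter
        self._r_t, self._g_t = self._scan_t(pop.mean_diameter)
        # brightness vs diameter at the mid shell
        t_mid = 0.5 * (pop.base_shell + pop.bound_shell)
        rb, gb = self._scan_d(t_mid)
        self._bright_d = (rb + gb) / np.interp(
            pop.mean_diameter, self._d_grid, rb + gb
        )
        if pop.size_dependent_contrast:
            self._r_dt = np.empty((len(self._d_grid), len(self._t_grid)))
            self._g_dt = np.empty_like(self._r_dt)
            for i, d in enumerate(self._d_grid):
                self._r_dt[i], self._g_dt[i] = self._scan_t(d)

    def _one(self, d, t):
        model = ParticleModel(d, t, self.pop.shell_index, self.pop.medium_index)
        spec = scattering_spectrum(model, self._grid, self.constants)
        bi = band_intensities(spec, self.bands)
        return bi.r_scat, bi.g_scat

    def _scan_t(self, d):
        vals = np.array([self._one(d, t) for t in self._t_grid])
        return vals[:, 0], vals[:, 1]

    def _scan_d(self, t):
        vals = np.array([self._one(d, t) for d in self._d_grid])
        return vals[:, 0], vals[:, 1]

    def band_photons(self, diameters, shells):
        """Expected (R, G) band intensities (nm^2 nm units) per particle."""
        d = np.asarray(diameters, dtype=float)
        t = np.asarray(shells, dtype=float)
        if self.pop.size_dependent_contrast:
            # bilinear interpolation over the (d, t) grid
            from scipy.interpolate import RegularGridInterpolator

            if not hasattr(self, "_interp_r"):
                self._interp_r = RegularGridInterpolator(
                    (self._d_grid, self._t_grid), self._r_dt, bounds_error=False, fill_value=None
                )
                self._interp_g = RegularGridInterpolator(
                    (self._d_grid, self._t_grid), self._g_dt, bounds_error=False, fill_value=None
                )
            pts = np.column_stack([d, t])
            return self._interp_r(pts), self._interp_g(pts)
        r = np.interp(t, self._t_grid, self._r_t)
        g = np.interp(t, self._t_grid, self._g_t)
        s = np.interp(d, self._d_grid, self._bright_d)
        return r * s, g * s


def _pixel_gaussian(shape, row, col, sigma, total):
    """Expected photon image of one spot: pixel-integrated 2-D Gaussian."""
    h, w = shape
    rad = int(np.ceil(4.5 * sigma))
    r0 = max(int(np.floor(row)) - rad, 0)
    r1 = min(int(np.floor(row)) + rad + 1, h)
    c0 = max(int(np.floor(col)) - rad, 0)
    c1 = min(int(np.floor(col)) + rad + 1, w)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    fr = ndtr((rows + 0.5 - row) / sigma) - ndtr((rows - 0.5 - row) / sigma)
    fc = ndtr((cols + 0.5 - col) / sigma) - ndtr((cols - 0.5 - col) / sigma)
    return (r0, r1, c0, c1), total * np.outer(fr, fc)


def _place_positions(n, shape, margin, min_sep, rng, max_tries=200):
    """Uniform random positions with a minimum pairwise separation."""
    h, w = shape
    pos = np.empty((n, 2))
    count = 0
    tries = 0
    while count < n:
        cand = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        if count == 0 or np.all(
            np.sum((pos[:count] - cand) ** 2, axis=1) >= min_sep**2
        ):
            pos[count] = cand
            count += 1
            tries = 0
        else:
            tries += 1
            if tries > max_tries * n:
                raise ConfigurationError(
                    f"cannot place {n} spots with separation {min_sep:.1f}px "
                    f"in a {h}x{w} frame"
                )
    return pos


def render_frames(
    particles: pd.DataFrame,
    pop: PopulationConfig,
    img: ImagingConfig,
    seed,
    bands: BandSet = NONADJACENT_BANDS,
    constants: OpticalConstants | None = None,
    table: BandResponseTable | None = None,
):
    """Render the particle table into R- and G-channel frame stacks.

    Particles are grouped ``spots_per_frame`` per frame.  Aggregates are
    drawn as two overlapping Gaussians (lobes 1.6 psf_sigma apart, photon
    budgets of two independently sized cores, shared shell).  Returns
    (r_stack, g_stack, ground_truth) with uint16 stacks and a DataFrame
    holding per-spot positions and the noiseless truth, including the true
    chromatic contrast gamma.
    """
    if table is None:
        table = BandResponseTable(pop, bands, constants)
    rng = np.random.default_rng(seed)
    n = len(particles)
    # an empty particle table still renders one background-only frame
    n_frames = max(int(np.ceil(n / img.spots_per_frame)), 1)
    h, w = img.frame_shape
    shell_inc = pop.bound_shell - pop.base_shell
    shells = particles["shell"].to_numpy() + shell_inc * particles["bound"].to_numpy()
    r1, g1 = table.band_photons(particles["diameter"].to_numpy(), shells)
    d2 = particles["diameter2"].to_numpy()
    agg = particles["is_aggregate"].to_numpy()
    r2 = np.zeros(n)
    g2 = np.zeros(n)
    if agg.any():
        r2[agg], g2[agg] = table.band_photons(d2[agg], shells[agg])
    scale = img.photons_per_unit_cross_section
    r_phot = scale * (r1 + r2)
    g_phot = scale * (g1 + g2)
    gamma_true = (r_phot - g_phot) / (r_phot + g_phot)

    bg_photons = img.background_level / img.adu_per_photon
    # spots closer than the background annulus outer radius would bias each
    # other's background estimate; keep them at least this far apart
    min_sep = img.min_separation_factor * img.psf_sigma
    half_sep = 0.8 * img.psf_sigma  # aggregate lobe half-offset

    r_stack = np.empty((n_frames, h, w), dtype=np.uint16)
    g_stack = np.empty((n_frames, h, w), dtype=np.uint16)
    records = []
    for f in range(n_frames):
        idx = np.arange(f * img.spots_per_frame, min((f + 1) * img.spots_per_frame, n))
        pos = _place_positions(len(idx), (h, w), img.edge_margin, min_sep, rng)
        r_img = np.full((h, w), bg_photons, dtype=float)
        g_img = np.full((h, w), bg_photons, dtype=float)
        for j, i in enumerate(idx):
            row, col = pos[j]
            if agg[i]:
                theta = rng.uniform(0, 2 * np.pi)
                dr, dc = half_sep * np.sin(theta), half_sep * np.cos(theta)
                lobes = [
                    (row + dr, col + dc, scale * r1[i], scale * g1[i]),
                    (row - dr, col - dc, scale * r2[i], scale * g2[i]),
                ]
            else:
                lobes = [(row, col, scale * r1[i], scale * g1[i])]
            for lr, lc, rp, gp in lobes:
                (a, b, c, d), patch = _pixel_gaussian((h, w), lr, lc, img.psf_sigma, 1.0)
                r_img[a:b, c:d] += rp * patch
                g_img[a:b, c:d] += gp * patch
            records.append(
                {
                    "particle_id": int(particles["particle_id"].iloc[i]),
                    "frame": f,
                    "row": row,
                    "col": col,
                    "diameter": particles["diameter"].iloc[i],
                    "shell": shells[i],
                    "is_aggregate": bool(agg[i]),
                    "bound": bool(particles["bound"].iloc[i]),
                    "gamma_true": gamma_true[i],
                    "r_photons": r_phot[i],
                    "g_photons": g_phot[i],
                }
            )
        for img_f, stack in ((r_img, r_stack), (g_img, g_stack)):
            if img.shot_noise:
                counts = rng.poisson(img_f).astype(float)
            else:
                counts = img_f
            adu = counts * img.adu_per_photon
            if img.read_noise_sd > 0:
                adu = adu + rng.normal(0.0, img.read_noise_sd, size=adu.shape)
            stack[f] = np.clip(np.rint(adu), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame.from_records(records)
    return r_stack, g_stack, truth


@dataclass
class SimulatedDataset:
    r_stack: np.ndarray
    g_stack: np.ndarray
    ground_truth: pd.DataFrame
    manifest: dict


def _config_hash(manifest: dict) -> str:
    blob = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def generate_dataset(
    concentration: float,
    n_spots: int = 15000,
    pop: PopulationConfig | None = None,
    binding: BindingModel | None = None,
    img: ImagingConfig | None = None,
    seed: int = 0,
    bands: BandSet = NONADJACENT_BANDS,
    constants: OpticalConstants | None = None,
    table: BandResponseTable | None = None,
) -> SimulatedDataset:
    """Simulate one detection condition at a given analyte concentration.

    Draws enough particles that the ground truth contains at least
    ``n_spots`` non-aggregate spots (the analysis quota per condition),
    assigns binding, and renders the two channel stacks.  Fully
    deterministic for a fixed seed.
    """
    if n_spots <= 0:
        raise ValueError("n_spots must be > 0")
    pop = pop or PopulationConfig()
    binding = binding or BindingModel()
    img = img or ImagingConfig()
    # inflate for the aggregate fraction, round up to whole frames, and
    # verify the non-aggregate quota on the actual draw
    n_particles = int(np.ceil(n_spots / max(1.0 - pop.aggregate_fraction, 1e-6)))
    while True:
        n_rounded = int(np.ceil(n_particles / img.spots_per_frame) * img.spots_per_frame)
        particles = sample_particles(n_rounded, pop, seed)
        if int((~particles["is_aggregate"]).sum()) >= n_spots:
            break
        n_particles = n_rounded + img.spots_per_frame
    particles = bind_analyte(particles, concentration, binding, seed + 1)
    r_stack, g_stack, truth = render_frames(
        particles, pop, img, seed + 2, bands, constants, table
    )
    manifest = {
        "concentration": concentration,
        "n_spots": n_spots,
        "seed": int(seed),
        "population": asdict(pop),
        "binding": asdict(binding),
        "imaging": asdict(img),
        "bands": {"g_band": list(bands.g_band), "r_band": list(bands.r_band)},
        "n_frames": int(r_stack.shape[0]),
        "n_particles": int(len(truth)),
    }
    manifest["config_hash"] = _config_hash(manifest)
    return SimulatedDataset(r_stack, g_stack, truth, manifest)


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write a dataset directory: multi-page 16-bit TIFF per channel,
    ground-truth CSV and a JSON manifest."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "r_stack.tif", ds.r_stack, photometric="minisblack")
    tifffile.imwrite(out / "g_stack.tif", ds.g_stack, photometric="minisblack")
    ds.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(ds.manifest, indent=2, default=str))
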