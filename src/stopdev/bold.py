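"""Forward model for synthetic 4-D BOLD runs.

Each voxel's signal is a sum over task conditions of a subject-specific
amplitude map times the HRF-convolved condition indicator, plus a
stop-specific psychophysiological coupling term confined to the target
(right STN) region, a slow linear drift, and Gaussian AR(1) noise. Six
motion parameters per volume are generated as smoothed random walks scaled
to a configurable maximum framewise displacement; they are nuisance
covariates only and do not corrupt the signal.

Subject amplitude maps interpolate between an adult template and a
subject-specific idiosyncratic field:

    child map_c = maturity * adult_template_c + (1 - maturity) * idio_c

so a child's activation pattern is adult-like exactly to the extent of the
latent maturity score. The STN response amplitude on stop conditions is set
by the subject's latent ``stn_amp``, and the seed->STN coupling on
successful stops by ``ppi_gain`` — the quantities the GLM / NMI / MVPA /
gPPI stages try to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import CONDITIONS, condition_regressor
from .grids import VolumeGrid
from .roi import ROISpec, sphere_mask

__all__ = [
    "NoiseSpec",
    "AmplitudeTemplates",
    "build_templates",
    "subject_amplitude_maps",
    "generate_bold_run",
    "generate_motion",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition noise model for synthetic runs.

    sigma is the AR(1) innovation scale in the same (arbitrary percent-signal)
    units as the amplitude templates; rho the lag-1 autocorrelation; drift a
    uniformly random linear trend with this peak-to-peak amplitude; the
    motion walk is scaled so max framewise displacement lands in ``fd_range``
    (mm).
    """

    sigma: float = 1.0
    ar_rho: float = 0.3
    drift_amplitude: float = 0.5
    fd_range: tuple[float, float] = (0.1, 0.8)


def _smooth_field(grid: VolumeGrid, rng: np.random.Generator,
                  smooth_vox: float = 1.5) -> np.ndarray:
    """Smooth unit-variance Gaussian random field on the gray mask."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.normal(size=grid.shape), smooth_vox)
    f /= f[grid.gray_mask].std()
    f[~grid.gray_mask] = 0.0
    return f


def _blob(grid: VolumeGrid, center_mm, fwhm_mm: float = 10.0) -> np.ndarray:
    """Gaussian bump (peak 1) around a mm-space center, zero outside gray."""
    coords = grid.voxel_coordinates_mm()
    d2 = ((coords - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=-1)
    sigma = fwhm_mm / 2.3548
    b = np.exp(-d2 / (2 * sigma ** 2))
    b[~grid.gray_mask] = 0.0
    return b


@dataclass
class AmplitudeTemplates:
    """Adult per-condition amplitude maps plus the STN stop profile.

    ``maps`` maps condition -> 3-D amplitude field (the adult template).
    ``stn_profile`` is the unit-amplitude stop response inside the STN
    spheres, scaled per subject by the latent ``stn_amp``. ``roi_masks``
    caches the sphere masks used by the generator.
    """

    maps: dict[str, np.ndarray]
    stn_profile: np.ndarray
    roi_masks: dict[str, np.ndarray]
    grid: VolumeGrid


def build_templates(grid: VolumeGrid, roi_set: list[ROISpec],
                    seed: int = 12345) -> AmplitudeTemplates:
    """Construct the adult activation templates on a synthetic grid.

    The successful-stop template carries positive bumps at the cortical
    inhibitory-control nodes (strongest at rAI), deactivation in a
    default-mode-like medial-posterior zone, a smooth random field over gray
    matter for voxel-level pattern richness, and a unit STN response. Go
    activates sensorimotor cortex; unsuccessful stops share a scaled-down
    cortical stop pattern. The template seed is fixed: the adult pattern is a
    property of the study, not of the cohort draw.
    """
    rng = np.random.default_rng(seed)
    masks = {spec.name: sphere_mask(spec, grid) for spec in roi_set}
    centers = {spec.name: spec.center for spec in roi_set}

    cortical_gain = {"rAI": 1.4, "rIFG": 1.2, "rMFG": 0.9, "rPreSMA": 1.0,
                     "rSMG": 0.8, "rCau": 0.7}
    stop = 0.6 * _smooth_field(grid, rng)
    for name, gain in cortical_gain.items():
        if name in centers:
            stop += gain * _blob(grid, centers[name])
    # default-mode-like deactivation: midline posterior zone
    shape = np.asarray(grid.shape)
    mid = (grid.affine @ np.array([(shape[0] - 1) / 2, 1.5,
                                   (shape[2] - 1) / 2 + 1, 1.0]))[:3]
    stop -= 1.0 * _blob(grid, mid, fwhm_mm=14.0)

    stn_profile = np.zeros(grid.shape)
    for name in ("rSTN", "lSTN"):
        if name in masks:
            stn_profile[masks[name]] = 1.0
    stop_full = stop + stn_profile

    go = 0.4 * _smooth_field(grid, rng)
    go[grid.sensorimotor_mask] += 1.0
    go_error = 0.3 * _smooth_field(grid, rng)
    unsucc = 0.7 * stop + stn_profile

    maps = {"Go": go, "GoError": go_error, "SuccStop": stop_full,
            "UnsuccStop": unsucc}
    for m in maps.values():
        m[~grid.gray_mask] = 0.0
    return AmplitudeTemplates(maps=maps, stn_profile=stn_profile,
                              roi_masks=masks, grid=grid)


def subject_amplitude_maps(
    templates: AmplitudeTemplates,
    maturity: float,
    stn_amp: float,
    rng: np.random.Generator,
    idiosyncratic_scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """Mix the adult template with an idiosyncratic field for one subject.

    Each condition map is ``maturity * template + (1 - maturity) * idio``,
    where the idiosyncratic field is a subject-specific smooth random field
    with the template's own scale times ``idiosyncratic_scale``. The STN stop
    response is then overwritten with ``stn_amp`` times the unit STN profile
    so the latent amplitude is exact by construction.
    """
    grid = templates.grid
    stn = templates.stn_profile > 0
    out = {}
    for cond, template in templates.maps.items():
        scale = idiosyncratic_scale * template[grid.gray_mask].std()
        idio = scale * _smooth_field(grid, rng)
        amp = maturity * template + (1.0 - maturity) * idio
        if cond in ("SuccStop", "UnsuccStop"):
            amp[stn] = stn_amp * templates.stn_profile[stn]
        out[cond] = amp
    return out


def generate_motion(n_scans: int, noise: NoiseSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Six smoothed random-walk motion parameters scaled to a target max FD."""
    steps = rng.normal(size=(n_scans, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    for k in range(6):
        walk[:, k] = np.convolve(walk[:, k], kernel, mode="same")
    walk[:, 3:] /= 50.0  # rotations in radians, on the 50 mm arc convention
    d = np.abs(np.diff(walk, axis=0))
    fd_max = (d[:, :3].sum(axis=1) + 50.0 * d[:, 3:].sum(axis=1)).max()
    target = rng.uniform(*noise.fd_range)
    return walk * (target / fd_max if fd_max > 0 else 1.0)


def _ar1_noise(shape_t: tuple[int, int], rho: float, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    """(n_voxels, n_scans) stationary AR(1) noise."""
    n_vox, n_scans = shape_t
    eps = rng.normal(scale=sigma, size=(n_vox, n_scans))
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0] / np.sqrt(1 - rho ** 2)
    for t in range(1, n_scans):
        out[:, t] = rho * out[:, t - 1] + eps[:, t]
    return out


def generate_bold_run(
    amplitude_maps: dict[str, np.ndarray],
    events: pd.DataFrame,
    grid: VolumeGrid,
    tr: float,
    n_scans: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
    ppi_gain: float = 0.0,
    ppi_seed_mask: np.ndarray | None = None,
    ppi_target_mask: np.ndarray | None = None,
    ppi_condition: str = "SuccStop",
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one (x, y, z, t) BOLD run plus its motion table.

    The coupling term adds ``ppi_gain * s * centered(convolved ppi_condition
    regressor)`` to every target voxel, where ``s`` is the seed region's task
    signal residualized against the run's motion parameters and intercept and
    then centered — the same cleaning the connectivity analysis applies when
    extracting a seed series, so on noiseless data the gain is the exact
    regression coefficient of the reconstructed interaction regressor.

    Raises
    ------
    ValueError
        On amplitude-map/grid shape mismatch or events beyond the run end.
    """
    for cond, amp in amplitude_maps.items():
        if amp.shape != grid.shape:
            raise ValueError(f"amplitude map {cond!r} shape {amp.shape} != "
                             f"grid {grid.shape}")
    if (events["onset"] >= n_scans * tr).any():
        raise ValueError("events fall beyond the run end")

    regressors = {}
    for cond in CONDITIONS:
        sel = events[events["trial_type"] == cond]
        if len(sel):
            regressors[cond] = condition_regressor(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(), tr, n_scans)

    motion = generate_motion(n_scans, noise, rng)

    n_vox = grid.n_voxels
    signal = np.zeros((n_vox, n_scans))
    for cond, reg in regressors.items():
        amp = amplitude_maps.get(cond)
        if amp is not None:
            signal += amp.reshape(-1, 1) * reg[None, :]

    if ppi_gain != 0.0 and ppi_seed_mask is not None and ppi_target_mask is not None:
        if ppi_condition not in regressors:
            raise ValueError(f"PPI condition {ppi_condition!r} has no events")
        seed_sig = signal.reshape(grid.shape + (n_scans,))[ppi_seed_mask].mean(axis=0)
        nuis = np.column_stack([motion, np.ones(n_scans)])
        coef, *_ = np.linalg.lstsq(nuis, seed_sig, rcond=None)
        seed_c = seed_sig - nuis @ coef
        seed_c -= seed_c.mean()
        reg = regressors[ppi_condition]
        inter = seed_c * (reg - reg.mean())
        signal.reshape(grid.shape + (n_scans,))[ppi_target_mask] += ppi_gain * inter

    if noise.sigma > 0:
        signal += _ar1_noise((n_vox, n_scans), noise.ar_rho, noise.sigma, rng)
    if noise.drift_amplitude > 0:
        slopes = rng.uniform(-noise.drift_amplitude, noise.drift_amplitude, n_vox)
        t = np.linspace(-0.5, 0.5, n_scans)
        signal += slopes[:, None] * t[None, :]

    return signal.reshape(grid.shape + (n_scans,)), motion
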