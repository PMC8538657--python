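"""Ground-truthed synthetic 4D renal DCE-MRI phantoms.

Every downstream stage of the pipeline (coarse segmentation, voxel
classification, pharmacokinetic fitting) is testable against these
phantoms because the compartment time-courses are produced by the same
forward 2CFM that the fitting stage inverts.

Geometry: two ellipsoidal "kidneys" placed left/right of the volume
midline, each partitioned concentrically into an outer cortical shell,
an inner medullary shell and a central pelvis, with shell radii chosen
so the voxel mix approximates the 58/31/11 cortex/medulla/pelvis split
observed in annotated clinical data.  A small aortic cylinder near the
midline carries the arterial input function, so AIF-from-ROI extraction
can be exercised.

Dynamics: cortex and medulla follow the two-compartment filtration
model driven by a gamma-variate-plus-washout population AIF (cortex:
early sharp uptake; medulla: delayed steady rise).  The pelvis collects
contrast at the excretory phase and is not a filtration compartment; it
is modelled as a delayed sigmoid accumulation.  Concentrations are
turned into signals with the spoiled-gradient-echo steady-state
equation and optionally corrupted by Gaussian or Rician noise.

Optionally, ``pk_dispersion`` adds within-compartment physiological
heterogeneity: each voxel draws one of ``n_dispersion_levels`` jittered
parameter sets per compartment (real parenchyma is not a single
time-course).  The default is 0, i.e. perfectly homogeneous
compartments whose noiseless voxels reproduce the forward model to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import pk
from .dataio import AIFCurve, CompartmentLabelMap, DynamicSeries, KidneyMask
from .errors import ConfigurationError, FormatError, GeometryError, ParameterError
from .pk import PKParams, concentration_to_signal

__all__ = [
    "AIFParams",
    "PelvisParams",
    "PhantomConfig",
    "PhantomOutput",
    "population_aif",
    "concentration_to_signal",
    "add_noise",
    "make_phantom",
]


@dataclass
class AIFParams:
    """Population arterial input function: gamma-variate bolus + recirculation washout.

    ``amplitude`` scales the whole curve linearly (peak first-pass
    concentration, mmol/L); ``bolus_arrival_s`` is the time the bolus
    reaches the aorta — by default the first post-baseline frame.
    """

    amplitude: float = 5.0
    bolus_arrival_s: float = 18.4
    alpha: float = 2.5          # gamma-variate shape
    t_peak_s: float = 9.0       # time-to-peak after arrival
    recirc_fraction: float = 0.24
    tau_rise_s: float = 4.0
    tau_decay_s: float = 80.0

    def validate(self) -> None:
        for name in ("alpha", "t_peak_s", "tau_rise_s", "tau_decay_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"AIF shape parameter {name} must be positive")
        if self.amplitude < 0 or self.recirc_fraction < 0:
            raise ParameterError("AIF amplitude and recirculation fraction must be non-negative")


@dataclass
class PelvisParams:
    """Late excretory accumulation surrogate: a delayed sigmoid."""

    onset_s: float = 100.0      # absolute time of half-maximal accumulation
    tau_s: float = 20.0         # sigmoid time constant
    cmax_mmol_l: float = 3.0    # late plateau concentration


@dataclass
class PhantomConfig:
    """Everything needed to generate one synthetic subject (deterministic given seed)."""

    shape: tuple[int, int, int] = (192, 192, 30)
    spacing_mm: tuple[float, float, float] = (2.2, 2.2, 3.0)
    n_frames: int = 74
    frame_interval_s: float = 2.3
    n_baseline_frames: int = 8
    cortex: PKParams = field(default_factory=lambda: PKParams(0.25, 0.40, 1.5, 4.0))
    medulla: PKParams = field(default_factory=lambda: PKParams(0.30, 0.20, 3.0, 30.0))
    pelvis: PelvisParams = field(default_factory=PelvisParams)
    aif: AIFParams | None = None
    t10_s: dict = field(default_factory=lambda: dict(pk.DEFAULT_T10_S))
    r1: float = pk.DEFAULT_R1
    flip_angle_deg: float = 20.0
    tr_ms: float = 2.36
    te_ms: float = 0.8
    noise_sigma: float = 0.03           # fraction of mean baseline signal
    noise_model: str = "gaussian"       # {"gaussian", "rician"}
    seed: int = 0
    kidney_semiaxes_vox: tuple[float, float, float] | None = None
    geometry_jitter: float = 0.05       # relative semi-axis jitter per subject
    pk_dispersion: float = 0.0          # fractional within-compartment PK jitter
    n_dispersion_levels: int = 24
    s0_kidney: float = 100.0
    s0_background: float = 60.0
    include_aorta: bool = True
    aorta_radius_vox: float = 3.0
    #: shell radii (relative) separating pelvis|medulla and medulla|cortex;
    #: 0.479^3 ~ 0.11 and 1 - 0.748^3 ~ 0.58 give the 58/31/11 class mix.
    r_pelvis: float = 0.479
    r_medulla: float = 0.748

    def validate(self) -> None:
        if self.n_baseline_frames >= self.n_frames:
            raise ConfigurationError("n_baseline_frames must be smaller than n_frames")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("voxel spacing must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError(f"unknown noise model '{self.noise_model}'")
        for name in ("cortex", "medulla"):
            params: PKParams = getattr(self, name)
            if not params.within_bounds():
                raise ConfigurationError(f"{name} PK parameters outside physiological bounds")

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def default_aif(self) -> AIFParams:
        if self.aif is not None:
            return self.aif
        return AIFParams(bolus_arrival_s=self.n_baseline_frames * self.frame_interval_s)


@dataclass
class PhantomOutput:
    """A generated subject with full ground truth."""

    series: DynamicSeries
    labels: CompartmentLabelMap
    left_mask: KidneyMask
    right_mask: KidneyMask
    aorta_mask: np.ndarray
    aif: AIFCurve
    true_params: dict
    cortex_volume_ml: dict
    sk_gfr_ml_min: dict
    config: PhantomConfig
    compartment_curves: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def population_aif(times, params: AIFParams | None = None) -> AIFCurve:
    """Evaluate the population AIF model at the given times (s).

    Zero before bolus arrival; gamma-variate first pass plus a slower
    recirculation/washout term; linear in ``amplitude``.
    """
    params = params or AIFParams()
    params.validate()
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise FormatError("times must be non-decreasing")
    tau = times - params.bolus_arrival_s
    with np.errstate(invalid="ignore"):
        rel = np.maximum(tau, 0.0) / params.t_peak_s
        gamma = rel**params.alpha * np.exp(params.alpha * (1.0 - rel))
        washout = (
            params.recirc_fraction
            * (1.0 - np.exp(-np.maximum(tau, 0.0) / params.tau_rise_s))
            * np.exp(-np.maximum(tau, 0.0) / params.tau_decay_s)
        )
    conc = params.amplitude * np.where(tau < 0, 0.0, gamma + washout)
    return AIFCurve(times=times, concentration=conc)


def pelvis_curve(times, params: PelvisParams, arrival_s: float) -> np.ndarray:
    """Delayed sigmoid accumulation; exactly zero up to bolus arrival."""
    times = np.asarray(times, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-(times - params.onset_s) / params.tau_s))
    sig0 = 1.0 / (1.0 + np.exp(-(arrival_s - params.onset_s) / params.tau_s))
    curve = params.cmax_mmol_l * np.maximum(sig - sig0, 0.0) / (1.0 - sig0)
    return np.where(times < arrival_s, 0.0, curve)


def add_noise(series: DynamicSeries, sigma: float, model: str = "gaussian", seed: int = 0) -> DynamicSeries:
    """Add measurement noise scaled to the mean baseline signal.

    gaussian: additive N(0, sigma*S0_mean), clipped at zero (magnitude
    images are non-negative); rician: magnitude of (S + n1, n2) with
    both components N(0, sigma*S0_mean).
    """
    if sigma < 0:
        raise ParameterError("noise sigma must be non-negative")
    if model not in ("gaussian", "rician"):
        raise ConfigurationError(f"unknown noise model '{model}'")
    if sigma == 0:
        return replace(series, data=series.data.copy())
    rng = np.random.default_rng(seed)
    scale = sigma * float(series.data[..., : series.n_baseline_frames].mean())
    if model == "gaussian":
        noisy = series.data + rng.normal(0.0, scale, series.data.shape)
        noisy = np.maximum(noisy, 0.0)
    else:
        n1 = rng.normal(0.0, scale, series.data.shape)
        n2 = rng.normal(0.0, scale, series.data.shape)
        noisy = np.hypot(series.data + n1, n2)
    return replace(series, data=noisy)


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def _ellipsoid_rho(shape, center, semiaxes) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel (<=1 inside)."""
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return np.sqrt(
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    )


def _jittered(value: float, rng: np.random.Generator, rel: float) -> float:
    return value * (1.0 + rel * rng.uniform(-1.0, 1.0))


def _dispersed_params(base: PKParams, rng, n_levels, rel) -> list[PKParams]:
    lo, hi = pk._bounds_arrays(pk.DEFAULT_TG_MAX_S)
    out = []
    for _ in range(n_levels):
        x = base.as_array() * (1.0 + rel * rng.uniform(-1.0, 1.0, 4))
        out.append(PKParams.from_array(np.clip(x, lo, hi)))
    return out


def make_phantom(config: PhantomConfig | None = None) -> PhantomOutput:
    """Generate one synthetic subject; deterministic given ``config.seed``."""
    config = config or PhantomConfig()
    config.validate()
    nx, ny, nz = config.shape
    rng = np.random.default_rng(config.seed)
    times = config.frame_times()
    aif_params = config.default_aif()
    aif = population_aif(times, aif_params)

    semi = config.kidney_semiaxes_vox or (17.0, 32.0, 0.4 * nz)
    centers = {"left": [nx // 4, ny // 2, nz / 2.0], "right": [3 * nx // 4, ny // 2, nz / 2.0]}
    boxes = {}
    labels = np.zeros(config.shape, dtype=np.uint8)
    masks = {}
    for side in ("left", "right"):
        axes = tuple(_jittered(s, rng, config.geometry_jitter) for s in semi)
        center = [c + rng.integers(-2, 3) for c in centers[side][:2]] + [centers[side][2]]
        x_lo, x_hi = center[0] - axes[0], center[0] + axes[0]
        half = (0, nx // 2) if side == "left" else (nx // 2, nx)
        if x_lo < half[0] or x_hi > half[1]:
            raise GeometryError(f"{side} kidney (x extent {x_lo:.0f}..{x_hi:.0f}) exceeds its half-volume")
        if center[1] - axes[1] < 0 or center[1] + axes[1] > ny or axes[2] > nz / 2.0 + 0.5:
            raise GeometryError(f"{side} kidney exceeds the volume matrix")
        boxes[side] = (x_lo, x_hi)
        rho = _ellipsoid_rho(config.shape, center, axes)
        masks[side] = rho <= 1.0
        labels[(rho <= 1.0) & (rho > config.r_medulla)] = 1
        labels[(rho <= config.r_medulla) & (rho > config.r_pelvis)] = 2
        labels[rho <= config.r_pelvis] = 3
    if boxes["left"][1] >= boxes["right"][0]:
        raise GeometryError("left and right kidneys overlap")

    aorta = np.zeros(config.shape, dtype=bool)
    if config.include_aorta:
        x, y = np.ogrid[:nx, :ny]
        disc = (x - nx // 2) ** 2 + (y - ny // 2 + 38) ** 2 <= config.aorta_radius_vox**2
        aorta = np.broadcast_to(disc[..., None], config.shape).copy()

    # compartment concentration curves at the frame times
    comp_conc = {
        "cortex": pk.forward_2cfm(config.cortex, aif).concentration,
        "medulla": pk.forward_2cfm(config.medulla, aif).concentration,
        "pelvis": pelvis_curve(times, config.pelvis, aif_params.bolus_arrival_s),
    }

    def to_signal(conc, tissue):
        return concentration_to_signal(
            conc, config.s0_kidney, config.t10_s[tissue], config.r1,
            config.tr_ms, config.flip_angle_deg,
        )

    data = np.empty(config.shape + (config.n_frames,))
    data[...] = config.s0_background
    level_maps = {}
    for code, tissue in ((1, "cortex"), (2, "medulla"), (3, "pelvis")):
        idx = labels == code
        if config.pk_dispersion > 0:
            n_lev = config.n_dispersion_levels
            if tissue == "pelvis":
                curves = []
                for _ in range(n_lev):
                    p = replace(
                        config.pelvis,
                        onset_s=config.pelvis.onset_s + config.pk_dispersion * 30.0 * rng.uniform(-1, 1),
                        cmax_mmol_l=_jittered(config.pelvis.cmax_mmol_l, rng, config.pk_dispersion),
                    )
                    curves.append(pelvis_curve(times, p, aif_params.bolus_arrival_s))
            else:
                psets = _dispersed_params(getattr(config, tissue), rng, n_lev, config.pk_dispersion)
                curves = [pk.forward_2cfm(p, aif).concentration for p in psets]
            assignment = rng.integers(0, n_lev, int(idx.sum()))
            level_maps[tissue] = assignment
            signals = np.stack([to_signal(c, tissue) for c in curves])
            data[idx] = signals[assignment]
        else:
            data[idx] = to_signal(comp_conc[tissue], tissue)
    if config.include_aorta:
        data[aorta] = concentration_to_signal(
            aif.concentration, config.s0_kidney, config.t10_s["blood"], config.r1,
            config.tr_ms, config.flip_angle_deg,
        )

    series = DynamicSeries(
        data=data,
        spacing=config.spacing_mm,
        frame_times=times,
        tr_ms=config.tr_ms,
        te_ms=config.te_ms,
        flip_angle_deg=config.flip_angle_deg,
        n_baseline_frames=config.n_baseline_frames,
    )
    if config.noise_sigma > 0:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        series = add_noise(series, config.noise_sigma, config.noise_model, seed=noise_seed)

    vox_ml = float(np.prod(config.spacing_mm)) / 1000.0
    cortex_volume_ml = {}
    sk_gfr = {}
    for side in ("left", "right"):
        n_cortex = int(((labels == 1) & masks[side]).sum())
        cortex_volume_ml[side] = n_cortex * vox_ml
        sk_gfr[side] = config.cortex.ktrans_per_min * cortex_volume_ml[side]

    return PhantomOutput(
        series=series,
        labels=CompartmentLabelMap(labels),
        left_mask=KidneyMask(masks["left"], side="left"),
        right_mask=KidneyMask(masks["right"], side="right"),
        aorta_mask=aorta,
        aif=aif,
        true_params={"cortex": config.cortex, "medulla": config.medulla, "pelvis": config.pelvis},
        cortex_volume_ml=cortex_volume_ml,
        sk_gfr_ml_min=sk_gfr,
        config=config,
        compartment_curves=comp_conc,
    )
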