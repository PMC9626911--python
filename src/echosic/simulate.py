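"""Synthetic echo-like images and synthetic cohorts.

Two generators make the whole analysis chain testable without access to the
(non-redistributable) source cohort:

* :func:`synth_echo_image` draws a speckle-textured frame with a horizontal
  "pericardial" band of controllable brightness, emulating the imaging
  substrate the texture score samples.  Speckle is multiplicative Rayleigh
  noise, the standard first-order model for fully developed ultrasound
  speckle; the per-region mean is calibrated so that the clipped, quantised
  pixel mean hits the requested target.

* :func:`synth_cohort` draws a subject-level cohort whose covariate
  marginals, covariate->HS-SIC regression structure, and sex-specific
  proportional-hazards structure match the defaults encoded in
  :class:`CohortSimConfig` (community-cohort values: n=2511, 56% women,
  ~3.7% heart-failure events over a 7.4 +/- 1.7 year horizon).  Event times
  are Weibull proportional hazards with the baseline scale calibrated by
  root finding so the expected observed-event fraction equals the target.

Every generator is a pure function of its config (fixed seed => identical
output).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from .imaging import GrayscaleImage, RegionOfInterest
from .texture import DEFAULT_LEVELS

__all__ = [
    "RAYLEIGH_UNIT_SCALE",
    "ImageSimConfig",
    "CohortSimConfig",
    "SimTruth",
    "synth_echo_image",
    "synth_cohort",
    "synth_image_cohort_link",
    "synth_mediation_cohort",
    "band_mean_from_sic",
]

#: Rayleigh scale giving a unit-mean multiplier: E[Rayleigh(s)] = s*sqrt(pi/2).
RAYLEIGH_UNIT_SCALE = math.sqrt(2.0 / math.pi)

_SIC_K = len(DEFAULT_LEVELS)
_SIC_MIN = _SIC_K / 256.0
_SIC_MAX = float(_SIC_K)


# --------------------------------------------------------------------------
# Images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimConfig:
    """Configuration of one synthetic echo-like frame.

    ``background_mean`` and ``band_mean`` are target pixel means (0-255) of
    the speckled background and of the bright/dark pericardial band spanning
    rows ``band_rows`` (half-open).  ``speckle_scale`` is the Rayleigh scale
    of the multiplicative speckle; the default gives a unit-mean multiplier.
    """

    height: int = 64
    width: int = 64
    background_mean: float = 40.0
    band_mean: float = 128.0
    band_rows: tuple[int, int] = (24, 40)
    speckle_scale: float = RAYLEIGH_UNIT_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_mean <= 255 and 0 <= self.band_mean <= 255):
            raise ValueError("target means must lie in [0, 255]")
        r0, r1 = self.band_rows
        if not (0 <= r0 < r1 <= self.height):
            raise ValueError(
                f"band_rows {self.band_rows} outside image of height {self.height}"
            )


def _rayleigh_clipped_mean(m: float, scale: float) -> float:
    """E[min(m*X, 255)] for X ~ Rayleigh(scale), in closed form."""
    if m <= 0:
        return 0.0
    t = 255.0 / m
    s = scale
    # partial mean E[X 1{X<t}] for Rayleigh
    part = s * math.sqrt(math.pi / 2.0) * erf(t / (s * math.sqrt(2.0))) \
        - t * math.exp(-t * t / (2.0 * s * s))
    tail = math.exp(-t * t / (2.0 * s * s))
    return m * part + 255.0 * tail


def _calibrated_region_mean(target: float, scale: float) -> float:
    """Pre-clip mean m such that the clipped pixel mean equals ``target``."""
    if target <= 0:
        return 0.0
    if target >= 255.0:
        # saturated band: push essentially every pixel to the clip ceiling
        return 1e9
    hi = 255.0
    while _rayleigh_clipped_mean(hi, scale) < target:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError(f"cannot calibrate region mean for target {target}")
    return brentq(lambda m: _rayleigh_clipped_mean(m, scale) - target, 1e-9, hi)


def synth_echo_image(
    cfg: ImageSimConfig,
) -> tuple[GrayscaleImage, RegionOfInterest, float]:
    """Draw a speckled frame with a pericardial band; return image, an ROI
    covering the band interior, and the expected band mean.

    The normalised Rayleigh multiplier has unit mean at the default scale, so
    the empirical band mean is within sampling error of ``band_mean`` (the
    pre-clip region mean is inflated to compensate for clipping at 255).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    scale = cfg.speckle_scale
    # normalise so E[multiplier] = 1 regardless of the configured scale
    mult = rng.rayleigh(scale=scale, size=(h, w)) / (scale * math.sqrt(math.pi / 2.0))
    unit_scale = RAYLEIGH_UNIT_SCALE
    means = np.full((h, w), _calibrated_region_mean(cfg.background_mean, unit_scale))
    r0, r1 = cfg.band_rows
    means[r0:r1, :] = _calibrated_region_mean(cfg.band_mean, unit_scale)
    pixels = np.clip(np.rint(means * mult), 0, 255).astype(np.uint8)
    image = GrayscaleImage(pixels, source_id=f"synth-echo-seed{cfg.seed}")
    # ROI strictly inside the band: inset 2 rows and w//8 columns
    inset_r = min(2, max(0, (r1 - r0 - 1) // 2))
    inset_c = w // 8
    roi = RegionOfInterest.rectangle(r0 + inset_r, r1 - inset_r, inset_c, w - inset_c)
    return image, roi, float(cfg.band_mean)


def band_mean_from_sic(hs_sic: float) -> float:
    """Invert the score formula: the band mean whose (noise-free) uniform
    intensity reproduces a target HS-SIC, ``256 * (1 - hs_sic / 5)``."""
    if not (_SIC_MIN <= hs_sic <= _SIC_MAX):
        raise ValueError(
            f"hs_sic={hs_sic} outside the feasible interval [{_SIC_MIN}, {_SIC_MAX}]"
        )
    return 256.0 * (1.0 - hs_sic / _SIC_K)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def _default_marginals() -> dict:
    """Covariate marginals of the emulated community cohort, by sex.

    Continuous entries are (mean, SD); binary entries are prevalences.
    """
    return {
        "age": {"kind": "continuous", "women": (65.8, 8.7), "men": (65.5, 8.8)},
        "bmi": {"kind": "continuous", "women": (27.6, 5.8), "men": (28.7, 4.5)},
        "sbp": {"kind": "continuous", "women": (128.0, 17.4), "men": (129.0, 16.6)},
        "dbp": {"kind": "continuous", "women": (72.6, 9.68), "men": (75.6, 9.99)},
        "tc_hdl_ratio": {"kind": "continuous", "women": (3.27, 0.95), "men": (3.74, 1.11)},
        "diabetes": {"kind": "binary", "women": 0.086, "men": 0.15},
        "smoker": {"kind": "binary", "women": 0.095, "men": 0.075},
        "egfr": {"kind": "continuous", "women": (79.7, 18.5), "men": (83.1, 17.5)},
        "antihtn_tx": {"kind": "binary", "women": 0.41, "men": 0.49},
        "lipid_tx": {"kind": "binary", "women": 0.35, "men": 0.44},
        "glucose_tx": {"kind": "binary", "women": 0.063, "men": 0.091},
        "lvef": {"kind": "continuous", "women": (69.0, 6.0), "men": (66.0, 7.0)},
        "e_over_eprime": {"kind": "continuous", "women": (7.37, 2.31), "men": (6.49, 1.95)},
        # RWT mean is a normal-range concentricity value; its SD anchors the
        # per-SD unit used downstream.
        "rwt": {"kind": "continuous", "women": (0.40, 0.0634), "men": (0.42, 0.0634)},
    }


def _default_sic_coefficients() -> dict:
    """Per-SD (continuous) / per-category (binary) effects on the HS-SIC scale."""
    return {
        "sex": -0.43,          # women vs men
        "age": 0.16,
        "bmi": 0.34,
        "tc_hdl_ratio": 0.15,
        "sbp": 0.04,
        "antihtn_tx": 0.21,
        "diabetes": 0.40,
        "smoker": 0.03,
        "lvef": -0.01,
        "e_over_eprime": 0.02,
    }


def _default_covariate_log_hrs() -> dict:
    """Log hazard ratios of the non-exposure covariates (per SD / per category).

    Values are plausible community-cohort effect sizes; the male excess is
    sized to reproduce the ~60/40 male/female split of events.
    """
    return {
        "sex": -0.69,          # women vs men: men carry ~2x the event hazard
        "age": 0.50,
        "bmi": 0.20,
        "sbp": 0.20,
        "tc_hdl_ratio": 0.10,
        "diabetes": 0.50,
        "smoker": 0.30,
        "antihtn_tx": 0.40,
    }


@dataclass
class CohortSimConfig:
    """Configuration of one synthetic cohort.

    Defaults encode the emulated study conditions: n=2511 subjects, 56%
    women, the covariate marginals of the source community cohort, the
    covariate->HS-SIC cross-sectional coefficients, sex-specific per-SD log
    hazard ratios for HS-SIC (women exp=1.67, men exp=1.16) and RWT (women
    1.17, men 1.55), administrative censoring at Normal(7.4, 1.7) years
    (floored at 0.5), and an expected event fraction of 94/2511.
    """

    n: int = 2511
    p_woman: float = 0.56
    covariate_marginals: dict = field(default_factory=_default_marginals)
    sic_intercept: float = 2.5
    sic_coefficients: dict = field(default_factory=_default_sic_coefficients)
    sic_noise_sd: float = 0.7
    log_hr_women: float = math.log(1.67)
    log_hr_men: float = math.log(1.16)
    log_hr_rwt_women: float = math.log(1.17)
    log_hr_rwt_men: float = math.log(1.55)
    covariate_log_hrs: dict = field(default_factory=_default_covariate_log_hrs)
    weibull_shape: float = 1.0
    followup_years: tuple[float, float] = (7.4, 1.7)
    min_followup_years: float = 0.5
    target_event_fraction: float = 94.0 / 2511.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not (0.0 < self.p_woman < 1.0):
            raise ValueError("p_woman must lie in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth behind a generated cohort: the exact parameters used,
    the calibrated baseline Weibull scale, and the uncensored event times."""

    config: dict
    baseline_weibull_scale: float
    uncensored_times: np.ndarray

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "baseline_weibull_scale": self.baseline_weibull_scale,
            "uncensored_times": np.asarray(self.uncensored_times).tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        return cls(
            config=payload["config"],
            baseline_weibull_scale=payload["baseline_weibull_scale"],
            uncensored_times=np.asarray(payload["uncensored_times"], dtype=float),
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance covariate in simulation")
    return (x - x.mean()) / sd


def synth_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a subject-level cohort table and its companion ground truth.

    Covariates are drawn from sex-specific marginals (continuous Gaussian,
    binary Bernoulli; independent given sex).  HS-SIC is a linear combination
    of sample-standardised covariates plus Gaussian noise, clipped to its
    feasible interval.  Event times are Weibull proportional hazards with a
    sex-specific per-SD HS-SIC (and RWT) effect; the baseline scale is
    solved so the expected observed-event fraction equals
    ``target_event_fraction`` under the drawn censoring horizons.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    sex = (rng.random(n) < cfg.p_woman).astype(int)  # 1 = woman
    women = sex == 1

    cols: dict[str, np.ndarray] = {"sex": sex}
    for name, spec in cfg.covariate_marginals.items():
        if spec["kind"] == "continuous":
            mw, sw = spec["women"]
            mm, sm = spec["men"]
            x = np.where(women,
                         rng.normal(mw, sw, n),
                         rng.normal(mm, sm, n))
        else:
            x = (rng.random(n) < np.where(women, spec["women"], spec["men"])).astype(int)
        cols[name] = x

    # HS-SIC: linear in standardised continuous covariates, raw binaries
    sic = np.full(n, cfg.sic_intercept, dtype=float)
    for name, beta in cfg.sic_coefficients.items():
        x = cols[name]
        kind = ("binary" if name == "sex"
                else cfg.covariate_marginals[name]["kind"])
        term = x if kind == "binary" else _zscore(np.asarray(x, dtype=float))
        sic = sic + beta * np.asarray(term, dtype=float)
    sic = sic + rng.normal(0.0, cfg.sic_noise_sd, n)
    n_clip = int(np.sum((sic < _SIC_MIN) | (sic > _SIC_MAX)))
    sic = np.clip(sic, _SIC_MIN, _SIC_MAX)
    cols["hs_sic"] = sic

    # linear predictor of the hazard
    z_sic = _zscore(sic)
    z_rwt = _zscore(np.asarray(cols["rwt"], dtype=float))
    lp = np.where(women, cfg.log_hr_women, cfg.log_hr_men) * z_sic
    lp = lp + np.where(women, cfg.log_hr_rwt_women, cfg.log_hr_rwt_men) * z_rwt
    for name, loghr in cfg.covariate_log_hrs.items():
        x = cols[name]
        kind = ("binary" if name == "sex"
                else cfg.covariate_marginals[name]["kind"])
        term = x if kind == "binary" else _zscore(np.asarray(x, dtype=float))
        lp = lp + loghr * np.asarray(term, dtype=float)
    lp = lp - lp.mean()

    mu, sd_f = cfg.followup_years
    censor = np.maximum(rng.normal(mu, sd_f, n), cfg.min_followup_years)

    k = cfg.weibull_shape
    target = cfg.target_event_fraction
    if not (0.0 < target < 1.0):
        raise ValueError(f"target_event_fraction={target} must lie in (0, 1)")
    elp = np.exp(lp)
    ck = censor ** k

    def expected_fraction(log_lam: float) -> float:
        return float(np.mean(1.0 - np.exp(-math.exp(log_lam) * ck * elp)))

    lo, hi = -30.0, 10.0
    f_lo, f_hi = expected_fraction(lo), expected_fraction(hi)
    if not (f_lo < target < f_hi):
        raise ValueError(
            f"target_event_fraction={target} infeasible under the configured "
            f"hazards/censoring (achievable range [{f_lo:.3g}, {f_hi:.3g}])"
        )
    log_lam = brentq(lambda x: expected_fraction(x) - target, lo, hi)
    lam = math.exp(log_lam)

    # inverse-CDF sampling of Weibull-PH event times
    u = rng.exponential(1.0, n)
    t_event = (u / (lam * elp)) ** (1.0 / k)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", [f"S{i:06d}" for i in range(n)])
    df["time"] = time
    df["event"] = event

    truth_cfg = asdict(cfg)
    truth_cfg["n_sic_clipped"] = n_clip
    truth = SimTruth(
        config=json.loads(json.dumps(truth_cfg, default=float)),
        baseline_weibull_scale=lam,
        uncensored_times=t_event,
    )
    return df, truth


# --------------------------------------------------------------------------
# Cohort -> image manifest
# --------------------------------------------------------------------------

def synth_image_cohort_link(
    cohort: pd.DataFrame,
    outdir: str | Path,
    template: Optional[ImageSimConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit one synthetic frame per subject whose band brightness encodes the
    subject's HS-SIC, so re-scoring the images approximately recovers the
    cohort's ``hs_sic`` column.

    The band mean is the inversion ``256 * (1 - hs_sic / 5)``.  Returns the
    scoring manifest (also written to ``outdir/manifest.csv``).
    """
    if "hs_sic" not in cohort.columns:
        raise ValueError("cohort has no hs_sic column")
    import imageio.v3 as iio

    template = template or ImageSimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cohort))]
    rows = []
    for (idx, rec), img_seed in zip(cohort.iterrows(), child_seeds):
        cfg = ImageSimConfig(
            height=template.height,
            width=template.width,
            background_mean=template.background_mean,
            band_mean=band_mean_from_sic(float(rec["hs_sic"])),
            band_rows=template.band_rows,
            speckle_scale=template.speckle_scale,
            seed=img_seed,
        )
        image, roi, _ = synth_echo_image(cfg)
        path = outdir / f"{rec['subject_id']}.png"
        iio.imwrite(path, image.pixels)
        (r0, c0), (r1, c1) = roi.vertices
        rows.append({
            "subject_id": rec["subject_id"],
            "image_path": str(path),
            "roi_type": "rectangle",
            "roi_coords": f"{r0:g},{r1:g},{c0:g},{c1:g}",
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# --------------------------------------------------------------------------
# Mediation scenario
# --------------------------------------------------------------------------

def synth_mediation_cohort(
    n: int = 50_000,
    a: float = 0.40,
    b: float = 0.015,
    c_direct: float = 0.0538,
    exposure_prevalence: float = 0.12,
    base_rate: float = 0.03,
    mediator_noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A minimal exposure -> mediator -> binary-outcome chain with known
    decomposition: indirect = a*b, direct = c_direct, total = c_direct + a*b.

    Defaults mirror a diabetes-like binary risk factor whose mediated
    fraction is a*b / (c_direct + a*b) ~= 0.10 on the event-probability
    scale.  The outcome is Bernoulli with a linear-probability mean.
    """
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < exposure_prevalence).astype(int)
    m = a * x + rng.normal(0.0, mediator_noise_sd, n)
    p = np.clip(base_rate + c_direct * x + b * m, 0.0, 1.0)
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"exposure": x, "mediator": m, "event": y})
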