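"""Circular statistics for directional and axial angle samples.

Collective polarity of a cell population is summarised by the resultant
vector of the per-cell unit vectors r_i = (cos a_i, sin a_i):

    r = (1/N) sum_i r_i,   R = ||r||  (polarity index, 0..1),

with mean direction abar = atan2(r_y, r_x), circular variance S = 1 - R and
the signed polarity index

    V = c * R,   c = cos(abar - alpha_p),

projecting the resultant onto a known reference ("polar") direction
alpha_p.  Axial data (period 180 deg, e.g. shape orientation) are analysed
after doubling theta_i = 2*phi_i and the mean is back-transformed as
phibar = thetabar / 2.

Uniformity tests: Rayleigh (omnibus), V-test (reference direction known a
priori), Watson's U^2 and Rao's spacing test (Monte-Carlo null).  All
angles are radians internally; the public API accepts and reports degrees
where suffixed ``_deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import special, stats

TWO_PI = 2.0 * math.pi

#: Resultant lengths below this leave the mean direction (and CI) undefined.
R_UNDEFINED_TOL = 1e-9

#: Bootstrap CI settings (used when the dispersion formula is invalid or n is small).
BOOTSTRAP_B = 2000
SMALL_SAMPLE_N = 25

#: Monte-Carlo settings for Rao's spacing null distribution.
RAO_MC_SAMPLES = 10_000
_RAO_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


@dataclass
class AngleSample:
    """A sample of directional (period 360 deg) or axial (period 180 deg) angles."""

    angles: np.ndarray                      # radians, normalised at ingestion
    mode: Literal["directional", "axial"] = "directional"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if a.size < 1:
            raise ValueError("need at least one angle")
        period = TWO_PI if self.mode == "directional" else math.pi
        self.angles = np.mod(a, period)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != self.angles.shape or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be nonnegative, same length, not all zero")
            self.weights = w

    @classmethod
    def from_degrees(
        cls,
        angles_deg,
        mode: Literal["directional", "axial"] = "directional",
        weights=None,
    ) -> "AngleSample":
        return cls(np.deg2rad(np.asarray(angles_deg, dtype=float)), mode, weights)

    @property
    def n(self) -> int:
        return self.angles.size

    def doubled(self) -> np.ndarray:
        """Angles on the directional scale: identity, or 2*phi for axial data."""
        if self.mode == "axial":
            return np.mod(2.0 * self.angles, TWO_PI)
        return self.angles


@dataclass
class CircSummary:
    n: int
    mode: str
    mean_deg: float            # mean direction (axial: back-transformed), NaN if R ~ 0
    R: float                   # polarity index (resultant length)
    S: float                   # circular variance, 1 - R
    V: float | None = None     # signed polarity index c*R
    c: float | None = None     # cos(mean - alpha_p)
    alpha_p_deg: float | None = None
    ci_low_deg: float | None = None
    ci_high_deg: float | None = None
    ci_level: float | None = None


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    reference_deg: float | None = None
    note: str = ""


def _resultant(theta: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Mean resultant length and mean direction of directional angles."""
    if weights is None:
        c, s = np.cos(theta).mean(), np.sin(theta).mean()
    else:
        w = weights / weights.sum()
        c, s = float(np.sum(w * np.cos(theta))), float(np.sum(w * np.sin(theta)))
    return float(np.hypot(c, s)), float(math.atan2(s, c))


def resultant_summary(sample: AngleSample) -> CircSummary:
    """Polarity index R, circular variance S = 1 - R and mean direction.

    Axial samples are summarised on the doubled angles and the mean is
    back-transformed (phibar = thetabar/2, reported in [0, 180)).
    """
    theta = sample.doubled()
    R, mean = _resultant(theta, sample.weights)
    if R < R_UNDEFINED_TOL:
        mean_deg = float("nan")
    elif sample.mode == "axial":
        mean_deg = math.degrees((mean / 2.0) % math.pi) % 180.0
    else:
        mean_deg = math.degrees(mean % TWO_PI) % 360.0
    return CircSummary(n=sample.n, mode=sample.mode, mean_deg=mean_deg, R=R, S=1.0 - R)


def signed_polarity_index(sample: AngleSample, alpha_p_deg: float) -> CircSummary:
    """Signed polarity index V = R*cos(abar - alpha_p) in [-1, 1].

    For axial samples both the angles and the reference are doubled.
    """
    theta = sample.doubled()
    R, mean = _resultant(theta, sample.weights)
    ref = math.radians(alpha_p_deg)
    if sample.mode == "axial":
        ref *= 2.0
    c = math.cos(mean - ref) if R >= R_UNDEFINED_TOL else 0.0
    out = resultant_summary(sample)
    out.alpha_p_deg = float(alpha_p_deg)
    out.c = c
    out.V = c * R
    return out


def _wrap_pi(x: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.mod(x + math.pi, TWO_PI) - math.pi


def mean_ci(
    sample: AngleSample,
    level: float = 0.95,
    n_boot: int = BOOTSTRAP_B,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the mean direction, in degrees.

    Uses the large-sample circular-dispersion interval
    ``abar +- asin(z * sqrt(dispersion/n))`` when n is large and the formula
    is valid; otherwise a seeded percentile bootstrap (B resamples of the
    circular mean, deviations wrapped around abar).  Returns (NaN, NaN)
    when R ~ 0 (the mean direction is undefined, the CI is the full circle).
    """
    theta = sample.doubled()
    n = theta.size
    if n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    R, mean = _resultant(theta)
    if R < R_UNDEFINED_TOL:
        return float("nan"), float("nan")

    half: float | None = None
    if n >= SMALL_SAMPLE_N:
        # circular dispersion (second trigonometric moment about the mean)
        rho2 = float(np.hypot(np.cos(2 * theta).mean(), np.sin(2 * theta).mean()))
        disp = (1.0 - rho2) / (2.0 * R * R)
        z = stats.norm.ppf(0.5 + level / 2.0)
        arg = z * math.sqrt(disp / n)
        if arg < 1.0:
            half = math.asin(arg)
    if half is None:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        cs = np.cos(theta)[idx].mean(axis=1)
        sn = np.sin(theta)[idx].mean(axis=1)
        boots = np.arctan2(sn, cs)
        dev = _wrap_pi(boots - mean)
        lo_dev, hi_dev = np.quantile(dev, [(1 - level) / 2, 0.5 + level / 2])
        lo, hi = mean + lo_dev, mean + hi_dev
    else:
        lo, hi = mean - half, mean + half

    if sample.mode == "axial":
        return (
            math.degrees((lo / 2.0) % math.pi) % 180.0,
            math.degrees((hi / 2.0) % math.pi) % 180.0,
        )
    return math.degrees(lo % TWO_PI) % 360.0, math.degrees(hi % TWO_PI) % 360.0


def ci_contains(angle_deg: float, lo_deg: float, hi_deg: float, period: float = 360.0) -> bool:
    """Whether an angle lies on the (wrapped) arc from lo to hi."""
    span = (hi_deg - lo_deg) % period
    return (angle_deg - lo_deg) % period <= span


# ---------------------------------------------------------------------------
# Uniformity tests
# ---------------------------------------------------------------------------

def rayleigh_test(sample: AngleSample) -> TestResult:
    """Rayleigh test of uniformity: Z = n*R^2, series-corrected p-value."""
    theta = sample.doubled()
    n = theta.size
    R, _ = _resultant(theta)
    Z = n * R * R
    p = math.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    note = "n < 4: p-value unreliable" if n < 4 else ""
    return TestResult("rayleigh", Z, float(np.clip(p, 0.0, 1.0)), n, note=note)


def v_test(sample: AngleSample, alpha_p_deg: float) -> TestResult:
    """V-test against a reference direction known a priori.

    The statistic is u = V * sqrt(2n) with V the signed polarity index; the
    one-sided p-value comes from the normal approximation.  V = 0 gives
    p = 0.5; anti-aligned samples (V < 0) give p > 0.5.
    """
    summ = signed_polarity_index(sample, alpha_p_deg)
    n = summ.n
    u = summ.V * math.sqrt(2.0 * n)
    p = float(stats.norm.sf(u))
    note = "n < 4: p-value unreliable" if n < 4 else ""
    return TestResult("v_test", u, p, n, reference_deg=float(alpha_p_deg), note=note)


def watson_test(sample: AngleSample) -> TestResult:
    """Watson's U^2 one-sample test of circular uniformity."""
    theta = np.sort(sample.doubled())
    n = theta.size
    u = theta / TWO_PI
    i = np.arange(1, n + 1)
    ubar = u.mean()
    u2 = float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1 / (12 * n) - n * (ubar - 0.5) ** 2)
    u2_mod = (u2 - 0.1 / n + 0.1 / (n * n)) * (1.0 + 0.8 / n)
    if u2_mod <= 1e-8:  # asymptotic series diverges; uniformity cannot be rejected
        p = 1.0
    else:
        j = np.arange(1, 51)
        p = float(
            2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * j * j * math.pi**2 * u2_mod))
        )
    note = "n < 4: p-value unreliable" if n < 4 else ""
    return TestResult("watson", u2, float(np.clip(p, 0.0, 1.0)), n, note=note)


def _rao_statistic_deg(theta: np.ndarray) -> float:
    """Rao's spacing statistic U = 1/2 sum |T_i - lambda| in degrees."""
    n = theta.size
    t = np.sort(np.mod(theta, TWO_PI))
    spacings = np.diff(t, append=t[0] + TWO_PI)
    lam = TWO_PI / n
    return math.degrees(0.5 * float(np.sum(np.abs(spacings - lam))))


def rao_spacing_test(
    sample: AngleSample, n_mc: int = RAO_MC_SAMPLES, seed: int = 0
) -> TestResult:
    """Rao's spacing test with a seeded Monte-Carlo null, cached per n.

    Exact critical-value tables are edition-dependent; the Monte-Carlo null
    (``n_mc`` uniform samples of the observed size) is reproducible and its
    resolution is controllable.  Ties (identical angles) produce zero
    spacings and reduce sensitivity; they are not an error.
    """
    theta = sample.doubled()
    n = theta.size
    u_obs = _rao_statistic_deg(theta)
    key = (n, n_mc, seed)
    if key not in _RAO_NULL_CACHE:
        rng = np.random.default_rng(seed)
        null = rng.uniform(0.0, TWO_PI, size=(n_mc, n))
        t = np.sort(null, axis=1)
        spacings = np.diff(np.concatenate([t, t[:, :1] + TWO_PI], axis=1), axis=1)
        lam = TWO_PI / n
        _RAO_NULL_CACHE[key] = np.degrees(0.5 * np.sum(np.abs(spacings - lam), axis=1))
    null_u = _RAO_NULL_CACHE[key]
    p = (1.0 + float(np.sum(null_u >= u_obs))) / (n_mc + 1.0)
    note = "n < 4: p-value unreliable" if n < 4 else ""
    return TestResult("rao_spacing", u_obs, p, n, note=note)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def circ_linear_corr(sample: AngleSample, x) -> float:
    """Mardia's circular-linear correlation coefficient in [0, 1].

    r^2 = (r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2) with the
    Pearson correlations of x with cos(a), sin(a) and of cos(a) with sin(a).
    NaN when x is constant or the angle sample is degenerate.
    """
    x = np.asarray(x, dtype=float)
    theta = sample.doubled()
    if x.size != theta.size:
        raise ValueError("x and angles must have equal length")
    if x.size < 5:
        raise ValueError("need n >= 5")
    c, s = np.cos(theta), np.sin(theta)
    if np.std(x) == 0 or np.std(c) == 0 or np.std(s) == 0:
        return float("nan")
    rxc = float(np.corrcoef(x, c)[0, 1])
    rxs = float(np.corrcoef(x, s)[0, 1])
    rcs = float(np.corrcoef(c, s)[0, 1])
    denom = 1.0 - rcs * rcs
    if denom <= 0:
        return float("nan")
    r2 = (rxc * rxc + rxs * rxs - 2.0 * rxc * rxs * rcs) / denom
    return float(math.sqrt(max(0.0, min(r2, 1.0))))


def circ_circ_corr(a: AngleSample, b: AngleSample) -> float:
    """Jammalamadaka-SenGupta circular-circular correlation in [-1, 1].

    rho = sum sin(a - abar) sin(b - bbar) /
          sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar));
    NaN when either sample is concentrated at a point (zero denominator).
    """
    ta, tb = a.doubled(), b.doubled()
    if ta.size != tb.size:
        raise ValueError("samples must have equal length")
    if ta.size < 5:
        raise ValueError("need n >= 5")
    _, ma = _resultant(ta)
    _, mb = _resultant(tb)
    sa, sb = np.sin(ta - ma), np.sin(tb - mb)
    denom = math.sqrt(float(np.sum(sa * sa)) * float(np.sum(sb * sb)))
    if denom == 0:
        return float("nan")
    return float(np.sum(sa * sb) / denom)


# ---------------------------------------------------------------------------
# Rose histogram
# ---------------------------------------------------------------------------

@dataclass
class RoseHistogram:
    counts: np.ndarray             # per-bin counts of the original data
    bin_edges_deg: np.ndarray      # n_bins + 1 edges over [0, 360]
    duplicated: np.ndarray | None  # axial: counts of the 180-deg-shifted copies


def rose_histogram(sample: AngleSample, n_bins: int = 24) -> RoseHistogram:
    """Counts over equal angular bins of the full circle.

    Axial samples occupy [0, 180); the duplicated half (each angle + 180
    deg) is returned separately so plots can show it transparent.  The
    non-duplicated counts always sum to n.
    """
    if n_bins < 4 or 360 % n_bins != 0:
        raise ValueError("n_bins must be >= 4 and divide 360")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    if sample.mode == "axial":
        deg = np.degrees(sample.angles) % 180.0
        counts, _ = np.histogram(deg, bins=edges)
        dup, _ = np.histogram((deg + 180.0) % 360.0, bins=edges)
        return RoseHistogram(counts=counts, bin_edges_deg=edges, duplicated=dup)
    deg = np.degrees(sample.angles) % 360.0
    counts, _ = np.histogram(deg, bins=edges)
    return RoseHistogram(counts=counts, bin_edges_deg=edges, duplicated=None)


def mean_resultant_length(kappa: float) -> float:
    """Theoretical mean resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    return float(special.i1e(kappa) / special.i0e(kappa))
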