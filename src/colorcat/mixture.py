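"""Mixture-model analysis of 4AFC color matches.

The classic descriptive pipeline for color-matching data: tally which colors
were offered and selected for each cue, fit each cue's selection-frequency
profile with a Gaussian-plus-floor, smooth the fitted peak offsets (the
"choice bias") around the hue circle, and read off color categories as
significant zero-crossings of the bias curve -- a negative-slope crossing is
an attractor (category center), a positive-slope crossing a repeller.

The per-cue model of selection frequency as a function of the hue separation
theta between a choice color and its cue is

    f(theta) = alpha * exp(-(theta - mu)^2 / (2 sigma^2)) + zeta

with peak height alpha, bias mu, width sigma, and guess floor zeta.  A plain
(unwrapped) Gaussian on theta in (-180, 180] is used rather than a circular
density: the empirical profiles reach an asymptotic floor well inside the
domain, which the zeta term absorbs.  Frequencies are normalized by offered
counts so the random foil sampling drops out, with offered counts as fit
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .colorspace import StimulusSet, circular_diff, wrap_angle
from .trials import TrialTable

__all__ = [
    "ChoiceTally",
    "CueFit",
    "MixtureFit",
    "PsychometricFit",
    "tally_choices",
    "fit_psychometric",
    "fit_mixture",
    "bias_curve",
    "find_zero_crossings",
    "analyze_mixture",
]

Z95 = 1.959963984540054

MU_BOUND = 90.0
SIGMA_RANGE = (2.0, 120.0)
ZETA_MAX = 0.5
#: multi-start grid for the per-cue fit
MU_STARTS = (-30.0, 0.0, 30.0)
SIGMA_STARTS = (15.0, 30.0)


@dataclass
class ChoiceTally:
    """Cue-by-color counts of offers and selections."""

    offered: np.ndarray
    selected: np.ndarray
    stimulus_set: StimulusSet

    @property
    def trials_per_cue(self) -> np.ndarray:
        return self.selected.sum(axis=1)


def tally_choices(trials: TrialTable) -> ChoiceTally:
    """Exact offer/selection counts per (cue, choice color)."""
    if trials.n_trials == 0:
        raise ValueError("cannot tally an empty trial table")
    n = trials.stimulus_set.n_colors
    offered = np.zeros((n, n), dtype=np.int64)
    selected = np.zeros((n, n), dtype=np.int64)
    np.add.at(offered, (trials.cue[:, None], trials.choices), 1)
    np.add.at(selected, (trials.cue, trials.selected_color), 1)
    return ChoiceTally(offered=offered, selected=selected, stimulus_set=trials.stimulus_set)


# ---------------------------------------------------------------------------
# psychometric function


@dataclass
class PsychometricFit:
    """Weibull performance curve y(omega) = zeta + (100 - zeta - gamma) *
    (1 - exp(-(omega / lam)^k)), with difficulty omega = hue distance from
    the cue to the nearest foil."""

    zeta: float
    gamma: float
    lam: float
    k: float
    lapse_rate: float
    omega: np.ndarray
    percent_correct: np.ndarray
    counts: np.ndarray
    se: np.ndarray | None = None  # standard errors of (zeta, gamma, lam, k)
    flagged: bool = False

    def predict(self, omega) -> np.ndarray:
        w = np.asarray(omega, dtype=float)
        return self.zeta + (100.0 - self.zeta - self.gamma) * (
            1.0 - np.exp(-((w / self.lam) ** self.k))
        )


def trial_difficulty(trials: TrialTable) -> np.ndarray:
    """Per-trial difficulty: hue distance from cue to its nearest foil."""
    hues = trials.stimulus_set.hue_angles
    d = np.abs(circular_diff(hues[trials.choices], hues[trials.cue][:, None]))
    d[d == 0] = np.inf  # the direct match is not a foil
    return d.min(axis=1)


def fit_psychometric(trials: TrialTable) -> PsychometricFit:
    """Least-squares Weibull fit of percent correct against difficulty.

    Trials are grouped by the exact difficulty values the stimulus grid
    induces; groups are weighted by trial count.  The lapse rate is the
    distance from perfect performance at the easiest difficulties (the top
    decile of omega, where the nearest foil is almost opposite the cue).
    """
    omega = trial_difficulty(trials)
    correct = trials.correct.astype(float)
    levels, inverse = np.unique(omega, return_inverse=True)
    counts = np.bincount(inverse)
    pct = 100.0 * np.bincount(inverse, weights=correct) / counts

    flagged = False
    p0 = (25.0, 5.0, 40.0, 2.0)
    bounds = ([0.0, 0.0, 1.0, 0.2], [100.0, 100.0, 400.0, 10.0])

    def weibull(w, z, g, lam, k):
        return z + (100.0 - z - g) * (1.0 - np.exp(-((w / lam) ** k)))

    se = None
    try:
        # two weighting passes: observed-proportion variances first, then
        # variances from the fitted curve (weighting by observed p(1-p)
        # upweights bins that fluctuated toward the extremes and biases the
        # asymptote; model-based variances remove that)
        p_clip = np.clip(pct / 100.0, 0.02, 0.98)
        popt = p0
        for _ in range(2):
            sigma = 100.0 * np.sqrt(p_clip * (1.0 - p_clip) / counts)
            popt, pcov = curve_fit(
                weibull, levels, pct, p0=popt, sigma=sigma,
                absolute_sigma=True, bounds=bounds, maxfev=20000,
            )
            p_clip = np.clip(weibull(levels, *popt) / 100.0, 0.02, 0.98)
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    except RuntimeError:
        popt = np.clip(p0, bounds[0], bounds[1])
        flagged = True
    if np.all(correct == correct[0]):
        flagged = True
    fit_ = PsychometricFit(
        zeta=float(popt[0]),
        gamma=float(popt[1]),
        lam=float(popt[2]),
        k=float(popt[3]),
        lapse_rate=0.0,
        omega=levels,
        percent_correct=pct,
        counts=counts,
        se=se,
        flagged=flagged,
    )
    easy = levels >= np.quantile(omega, 0.9)
    fit_.lapse_rate = float(100.0 - fit_.predict(levels[easy]).mean())
    return fit_


# ---------------------------------------------------------------------------
# per-cue mixture fit


@dataclass
class CueFit:
    """Gaussian-plus-floor fit of one cue's selection-frequency profile."""

    cue: int
    alpha: float
    mu: float
    sigma: float
    zeta: float
    se: np.ndarray  # standard errors of (alpha, mu, sigma, zeta)
    converged: bool

    @property
    def mu_ci(self) -> tuple[float, float]:
        return (self.mu - Z95 * self.se[1], self.mu + Z95 * self.se[1])


def _gauss_floor(theta, alpha, mu, sigma, zeta):
    return alpha * np.exp(-((theta - mu) ** 2) / (2.0 * sigma ** 2)) + zeta


def fit_mixture(tally: ChoiceTally, cue: int) -> CueFit:
    """Weighted nonlinear least squares of the per-cue selection profile.

    Fits selection frequency (selected / offered) against theta =
    hue(choice) - hue(cue) over a small multi-start grid in (mu, sigma).
    Points are weighted by their binomial standard errors (so offered counts
    set the weights, modulated by p(1-p)); 95% CIs come from the linearized
    covariance scaled by reduced chi-square, which keeps them honest when
    the Gaussian-plus-floor shape is only an approximation of the true
    profile.  Degenerate profiles (flat, or no convergence from any start)
    are returned with ``converged=False``.
    """
    offered = tally.offered[cue]
    selected = tally.selected[cue]
    mask = offered > 0
    if (selected[mask] > 0).sum() < 8:
        return CueFit(cue, 0.0, 0.0, SIGMA_RANGE[0], 0.0, np.full(4, np.inf), False)
    hues = tally.stimulus_set.hue_angles
    theta = circular_diff(hues[mask], hues[cue])
    freq = selected[mask] / offered[mask]
    # binomial standard error of each frequency; each cell's clip floor is
    # its own counting resolution, so rarely-offered empty cells keep an
    # error bar commensurate with their information content
    p_clip = np.clip(freq, 1.0 / (2.0 * offered[mask]), 0.95)
    w = np.sqrt(p_clip * (1.0 - p_clip) / offered[mask])

    best = None
    lower = [0.0, -MU_BOUND, SIGMA_RANGE[0], 0.0]
    upper = [1.0, MU_BOUND, SIGMA_RANGE[1], ZETA_MAX]
    for mu0 in MU_STARTS:
        for sigma0 in SIGMA_STARTS:
            try:
                popt, pcov = curve_fit(
                    _gauss_floor, theta, freq,
                    p0=(min(max(freq.max() - freq.min(), 0.05), 1.0), mu0, sigma0, freq.min()),
                    sigma=w, absolute_sigma=False, bounds=(lower, upper), maxfev=10000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum(((freq - _gauss_floor(theta, *popt)) / w) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
    if best is None:
        return CueFit(cue, 0.0, 0.0, SIGMA_RANGE[0], 0.0, np.full(4, np.inf), False)
    _, popt, pcov = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    # a usable fit needs a resolved peak: height clear of zero by its own
    # standard error and a width not pinned to the lower bound (narrow
    # spikes through single noisy points are guess-rate artifacts)
    degenerate = (
        popt[0] < 1e-2
        or not np.isfinite(se[1])
        or popt[0] < 2.0 * se[0]
        or popt[2] < SIGMA_RANGE[0] * 1.5
    )
    return CueFit(
        cue=cue,
        alpha=float(popt[0]),
        mu=float(popt[1]),
        sigma=float(popt[2]),
        zeta=float(popt[3]),
        se=se,
        converged=not degenerate,
    )


# ---------------------------------------------------------------------------
# bias curve and zero crossings


def _interpolate_failed(values: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Fill non-converged entries by linear interpolation around the ring."""
    if ok.all():
        return values
    n = len(values)
    idx = np.arange(n)
    good = np.flatnonzero(ok)
    # extend the good grid one period each way so interpolation wraps
    xg = np.concatenate([good - n, good, good + n])
    yg = np.tile(values[good], 3)
    out = values.copy()
    out[~ok] = np.interp(idx[~ok], xg, yg)
    return out


def bias_curve(fits: list[CueFit], min_converged: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Circular 3-point moving average of the raw per-cue biases.

    Returns ``(smoothed_bias, smoothed_se)``.  Non-converged cues are
    interpolated circularly before smoothing; their SEs are taken as the
    largest converged SE.  Raises if too few cues converged (default
    threshold: three quarters of the ring).
    """
    n = len(fits)
    ok = np.array([f.converged for f in fits])
    if min_converged is None:
        min_converged = (3 * n) // 4
    if ok.sum() < min_converged:
        raise ValueError(f"only {ok.sum()} of {n} cue fits converged (need {min_converged})")
    mu = np.array([f.mu for f in fits])
    se = np.array([f.se[1] for f in fits])
    mu = _interpolate_failed(mu, ok)
    se[~ok] = se[ok].max()
    smoothed = (np.roll(mu, 1) + mu + np.roll(mu, -1)) / 3.0
    smoothed_se = np.sqrt(np.roll(se, 1) ** 2 + se ** 2 + np.roll(se, -1) ** 2) / 3.0
    return smoothed, smoothed_se


@dataclass
class Crossing:
    """A zero-crossing of the smoothed bias curve."""

    angle: float
    kind: str  # "attractor" (negative slope) or "repeller" (positive slope)
    significant: bool
    ci: tuple[float, float] | None = None


def find_zero_crossings(
    smoothed_bias: np.ndarray,
    smoothed_se: np.ndarray,
    hue_angles: np.ndarray,
) -> list[Crossing]:
    """Locate bias zero-crossings by linear interpolation between cues.

    A crossing from positive to negative bias (negative slope) marks an
    attractor; positive slope marks a repeller.  A crossing is significant
    when the simultaneous 95% confidence band of the smoothed bias curve
    credibly clears zero on each side of it: within the same-sign lobe on
    each flank, at least one cue's band must exclude zero (with the lobe's
    sign).  The band is simultaneous over all cues (Sidak-corrected normal
    quantile), because a category claim is a statement about the whole
    curve; a pointwise band would certify noise wiggles on null data.  The
    cue immediately adjacent to a crossing necessarily sits near zero, so
    the evidence lives in the flanking lobes, not in the two straddling
    points.
    """
    from scipy.special import ndtri

    n = len(smoothed_bias)
    # simultaneous two-sided 95% band over n cues (Sidak)
    z_band = float(ndtri(1.0 - 0.5 * (1.0 - 0.95 ** (1.0 / n))))
    out: list[Crossing] = []

    def lobe_clears(start: int, direction: int, positive: bool) -> bool:
        j = start
        for _ in range(n):
            s = smoothed_bias[j % n]
            if s == 0.0 or (s > 0.0) != positive:
                return False
            lo = s - z_band * smoothed_se[j % n]
            hi = s + z_band * smoothed_se[j % n]
            if (positive and lo > 0.0) or (not positive and hi < 0.0):
                return True
            j += direction
        return False

    for k in range(n):
        k2 = (k + 1) % n
        s1, s2 = smoothed_bias[k], smoothed_bias[k2]
        if s1 > 0.0 >= s2:
            kind = "attractor"
        elif s1 < 0.0 <= s2:
            kind = "repeller"
        else:
            continue
        frac = s1 / (s1 - s2)
        step = circular_diff(hue_angles[k2], hue_angles[k])
        angle = float(wrap_angle(hue_angles[k] + frac * step))
        positive_first = kind == "attractor"
        significant = lobe_clears(k, -1, positive_first) and lobe_clears(
            k2, +1, not positive_first
        )
        out.append(Crossing(angle=angle, kind=kind, significant=significant))
    return out


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class MixtureFit:
    """Complete mixture-model analysis of one trial table."""

    cue_fits: list[CueFit]
    smoothed_bias: np.ndarray
    smoothed_se: np.ndarray
    crossings: list[Crossing]
    stimulus_set: StimulusSet
    n_trials: int
    seed: int | None = None

    @property
    def attractors(self) -> list[Crossing]:
        return [c for c in self.crossings if c.kind == "attractor"]

    @property
    def repellers(self) -> list[Crossing]:
        return [c for c in self.crossings if c.kind == "repeller"]

    def significant_attractors(self) -> list[Crossing]:
        return [c for c in self.attractors if c.significant]

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "seed": self.seed,
            "cues": [
                {
                    "cue": f.cue,
                    "alpha": f.alpha,
                    "mu": f.mu,
                    "sigma": f.sigma,
                    "zeta": f.zeta,
                    "se": f.se.tolist(),
                    "converged": f.converged,
                }
                for f in self.cue_fits
            ],
            "smoothed_bias": self.smoothed_bias.tolist(),
            "smoothed_se": self.smoothed_se.tolist(),
            "crossings": [
                {
                    "angle": c.angle,
                    "kind": c.kind,
                    "significant": c.significant,
                    "ci": list(c.ci) if c.ci is not None else None,
                }
                for c in self.crossings
            ],
        }


def analyze_mixture(
    trials: TrialTable, n_boot: int = 0, seed: int = 0
) -> MixtureFit:
    """Run the full mixture pipeline on a trial table.

    With ``n_boot > 0``, crossing-angle 95% CIs are estimated by a
    trial-level bootstrap: the table is resampled with replacement, the
    whole pipeline is re-run, and each original crossing's CI is the
    percentile interval of the matched crossing angles (matched by nearest
    angle, same kind, within half the inter-attractor spacing).
    """
    tally = tally_choices(trials)
    n = trials.stimulus_set.n_colors
    fits = [fit_mixture(tally, c) for c in range(n)]
    smoothed, se = bias_curve(fits)
    crossings = find_zero_crossings(smoothed, se, trials.stimulus_set.hue_angles)
    result = MixtureFit(
        cue_fits=fits,
        smoothed_bias=smoothed,
        smoothed_se=se,
        crossings=crossings,
        stimulus_set=trials.stimulus_set,
        n_trials=trials.n_trials,
        seed=seed if n_boot else None,
    )
    if n_boot > 0 and crossings:
        rng = np.random.default_rng(seed)
        samples: list[list[float]] = [[] for _ in crossings]
        for _ in range(n_boot):
            idx = rng.integers(0, trials.n_trials, trials.n_trials)
            boot = analyze_mixture(trials.subset(idx), n_boot=0)
            for j, c in enumerate(crossings):
                candidates = [
                    b for b in boot.crossings
                    if b.kind == c.kind and abs(circular_diff(b.angle, c.angle)) < 45.0
                ]
                if candidates:
                    nearest = min(candidates, key=lambda b: abs(circular_diff(b.angle, c.angle)))
                    samples[j].append(c.angle + circular_diff(nearest.angle, c.angle))
        for j, c in enumerate(crossings):
            if len(samples[j]) >= max(10, n_boot // 4):
                lo, hi = np.percentile(samples[j], [2.5, 97.5])
                c.ci = (float(wrap_angle(lo)), float(wrap_angle(hi)))
    return result
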