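"""Synthetic 4AFC agents with known ground-truth similarity structure.

Agents implement the same signal-detection choice rule as the TCC-v models:
on each trial the cue is drawn uniformly, three foils are drawn uniformly
without replacement from the remaining colors, the exact match is always
offered, and the agent picks the argmax of X_i ~ Normal(m_i * dprime, 1)
where m_i is its ground-truth similarity of choice i to the cue.  Because
the agent and the fitted models share the similarity/choice machinery, the
empirical selection frequencies of any agent converge to
:func:`colorcat.tccv.choice_probability` evaluated at the same parameters.

Three ground-truth variants mirror the model family: an unbiased agent
(``null``), an agent with cognitive color categories (``cognitive_bias``,
per-cue similarity peaks displaced toward attractor hues), and an agent
lacking categories whose stimuli nonuniformly sample an underlying uniform
space (``stimulus_nonuniformity``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .colorspace import StimulusSet, canonical_stimulus_set, circular_diff
from .tccv import TccvModel, similarity_matrix
from .trials import TrialTable

__all__ = [
    "GroundTruth",
    "generate_trials",
    "sample_choice",
    "make_fig3_scenarios",
    "attractor_offsets",
    "mean_bias_curve",
]

TRUTH_VARIANTS = ("null", "cognitive_bias", "stimulus_nonuniformity")


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic agent (see module docstring)."""

    variant: str
    sigma: float
    dprime: float
    offsets: np.ndarray | None = None
    distances: np.ndarray | None = None

    def __post_init__(self):
        if self.variant not in TRUTH_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dprime < 0:
            raise ValueError("dprime must be nonnegative")
        # delegate the remaining checks (distance positivity, 360 total)
        self.to_model()

    def to_model(self) -> TccvModel:
        return TccvModel(
            variant=self.variant,
            sigma=self.sigma,
            dprime=self.dprime,
            offsets=self.offsets,
            distances=self.distances,
        )

    def similarity_matrix(self, stimulus_set: StimulusSet) -> np.ndarray:
        return similarity_matrix(self.to_model(), stimulus_set)


def _sample_selections(m: np.ndarray, dprime: float, rng: np.random.Generator) -> np.ndarray:
    """Argmax of Normal(m * dprime, 1) evidence, row-wise; 1-based positions.

    Ties (measure-zero under the Gaussian, but possible after float
    rounding) break toward the lowest position via argmax.
    """
    evidence = m * dprime + rng.standard_normal(m.shape)
    return np.argmax(evidence, axis=1) + 1


def sample_choice(
    truth: GroundTruth,
    stimulus_set: StimulusSet,
    cue: int,
    choices,
    rng: np.random.Generator,
) -> int:
    """Sample the selected position (1..4) for a single trial."""
    S = truth.similarity_matrix(stimulus_set)
    m = S[cue, np.asarray(choices)][None, :]
    return int(_sample_selections(m, truth.dprime, rng)[0])


def generate_trials(
    truth: GroundTruth,
    stimulus_set: StimulusSet,
    n_trials: int,
    seed: int,
    session_id: str = "sim",
) -> TrialTable:
    """Generate a table of completed 4AFC trials from an agent.

    Cues are uniform over the color set; the three foils are uniform without
    replacement from the remaining colors; the four choices appear in random
    positions.  The same (truth, seed, n) always yields an identical table.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    n = stimulus_set.n_colors
    rng = np.random.default_rng(seed)
    cues = rng.integers(0, n, n_trials)
    # 3 uniform non-cue foils per trial: rank random keys with the cue masked
    keys = rng.random((n_trials, n))
    keys[np.arange(n_trials), cues] = 2.0
    foils = np.argpartition(keys, 3, axis=1)[:, :3]
    choices = np.concatenate([cues[:, None], foils], axis=1)
    # shuffle presentation positions
    order = np.argsort(rng.random((n_trials, 4)), axis=1)
    choices = np.take_along_axis(choices, order, axis=1)
    S = truth.similarity_matrix(stimulus_set)
    m = S[cues[:, None], choices]
    selected = _sample_selections(m, truth.dprime, rng)
    return TrialTable(
        cue=cues,
        choices=choices,
        selected=selected,
        stimulus_set=stimulus_set,
        session_id=np.full(n_trials, session_id, dtype=object),
        seed=seed,
    )


def sinusoidal_nonuniformity(
    stimulus_set: StimulusSet | None = None,
    amplitude: float = 0.45,
    cycles: int = 2,
    phase: float = 0.0,
    sigma: float = 20.0,
    dprime: float = 2.0,
) -> GroundTruth:
    """A smoothly warped, well-identified stimulus-nonuniformity truth.

    Neighbor distances follow ``D_k = (360/n) (1 + amplitude sin(2 pi
    cycles k / n + phase))``, normalized to a 360-degree total.  With the
    default amplitude every step stays well inside the similarity width, so
    all distances are strongly informed by the data -- the regime for
    parameter-recovery experiments (very wide gaps, beyond ~2 sigma, are
    intrinsically weakly identified because similarity is near zero across
    them either way).
    """
    sset = stimulus_set if stimulus_set is not None else canonical_stimulus_set()
    n = sset.n_colors
    k = np.arange(n)
    d = 1.0 + amplitude * np.sin(2.0 * np.pi * cycles * k / n + phase)
    d *= 360.0 / d.sum()
    return GroundTruth(
        variant="stimulus_nonuniformity", sigma=sigma, dprime=dprime, distances=d
    )


# ---------------------------------------------------------------------------
# the two matched mechanism scenarios


def attractor_offsets(
    stimulus_set: StimulusSet,
    attractors,
    amplitude: float = 10.0,
    ramp_scale: float = 30.0,
) -> np.ndarray:
    """Per-cue similarity-peak offsets induced by attractor hues.

    Each cue's offset is ``g(d)`` where ``d`` is the signed hue distance
    from the cue to its nearest attractor and ``g(d) = amplitude *
    tanh(d / ramp_scale)`` -- an odd, saturating ramp: cues are pulled
    toward the nearest category center, most strongly at intermediate
    distances, with sign flips (repellers) midway between attractors.
    """
    attractors = np.asarray(attractors, dtype=float)
    d = circular_diff(attractors[None, :], stimulus_set.hue_angles[:, None])
    nearest = np.argmin(np.abs(d), axis=1)
    dn = d[np.arange(len(d)), nearest]
    return amplitude * np.tanh(dn / ramp_scale)


def mean_bias_curve(S: np.ndarray, stimulus_set: StimulusSet) -> np.ndarray:
    """Similarity-weighted mean signed error per cue, in nominal hue degrees.

    The centroid of each cue's similarity function, measured in the nominal
    (CIELUV) hue coordinates a mixture analysis sees; both mechanism
    scenarios are matched on this curve.
    """
    hues = stimulus_set.hue_angles
    delta = circular_diff(hues[None, :], hues[:, None])
    return (S * delta).sum(axis=1) / S.sum(axis=1)


@lru_cache(maxsize=4)
def _solve_matched_distances(
    n_colors: int, sigma: float, attractors: tuple, amplitude: float, ramp_scale: float
) -> np.ndarray:
    """Least-squares distances whose warped-space mean-bias curve matches the
    attractor scenario's curve on all cues."""
    sset = canonical_stimulus_set() if n_colors == 64 else None
    if sset is None or sset.n_colors != n_colors:
        from .colorspace import build_stimulus_set

        sset = build_stimulus_set(n_colors=n_colors)
    offsets = attractor_offsets(sset, attractors, amplitude, ramp_scale)
    target = mean_bias_curve(
        similarity_matrix(
            TccvModel("cognitive_bias", sigma=sigma, dprime=1.0, offsets=offsets), sset
        ),
        sset,
    )

    def residual(logits):
        e = np.exp(np.concatenate([[0.0], logits]))
        distances = 360.0 * e / e.sum()
        S = similarity_matrix(
            TccvModel("stimulus_nonuniformity", sigma=sigma, dprime=1.0,
                      distances=distances), sset
        )
        return mean_bias_curve(S, sset) - target

    sol = least_squares(residual, np.zeros(n_colors - 1), method="lm")
    e = np.exp(np.concatenate([[0.0], sol.x]))
    return 360.0 * e / e.sum()


def make_fig3_scenarios(
    stimulus_set: StimulusSet | None = None,
    attractors=(17.0, 212.0),
    sigma: float = 20.0,
    dprime: float = 2.0,
    amplitude: float = 10.0,
    ramp_scale: float = 30.0,
) -> tuple[GroundTruth, GroundTruth]:
    """The two mechanism scenarios that a mixture analysis cannot tell apart.

    Returns ``(cognitive, nonuniform)``: an agent with two category
    attractors (default near 17 and 212 degrees), and a category-free agent
    whose stimulus spacing is solved numerically so its mean-bias curve
    matches the attractor agent's on every cue.  The attractor agent's
    similarity functions keep a constant width with shifted peaks; the
    warped agent's similarity matrix stays symmetric about the diagonal but
    bulges where the nominal space oversamples the underlying uniform space.

    A mixture analysis places its bias zero-crossings at the same angles
    for both scenarios.  The fitted peak amplitude is smaller for the
    warped agent (a warp displaces the profile's centroid more than its
    peak), so at matched trial counts its crossings carry weaker
    significance than the attractor agent's -- only likelihood modeling of
    the full profile shape separates the two mechanisms cleanly.
    """
    sset = stimulus_set if stimulus_set is not None else canonical_stimulus_set()
    offsets = attractor_offsets(sset, attractors, amplitude, ramp_scale)
    cognitive = GroundTruth(
        variant="cognitive_bias", sigma=sigma, dprime=dprime, offsets=offsets
    )
    distances = _solve_matched_distances(
        sset.n_colors, sigma, tuple(float(a) for a in attractors), amplitude, ramp_scale
    )
    nonuniform = GroundTruth(
        variant="stimulus_nonuniformity", sigma=sigma, dprime=dprime, distances=distances
    )
    return cognitive, nonuniform
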