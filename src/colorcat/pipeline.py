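"""End-to-end orchestration: I/O, validation, subsampling, and full runs.

A run ties the stages together in the order the analysis narrative uses
them: load or simulate trials -> tally and mixture analysis -> TCC-v fits
-> model comparison (optionally bootstrapped) -> uniform-space map from the
winning nonuniformity fit.  Every output JSON embeds the package version, a
hash of the configuration, and all seeds, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import GroundTruth, generate_trials, make_fig3_scenarios
from .colorspace import StimulusSet, canonical_stimulus_set
from .mixture import analyze_mixture
from .mucs import derive_map, sample_uniform_mucs
from .tccv import bootstrap_compare, fit
from .trials import TrialTable

__all__ = [
    "RunConfig",
    "run_pipeline",
    "validate_trials",
    "subsample_equal",
    "truth_for_variant",
]

logger = logging.getLogger("colorcat")

VARIANT_ALIASES = {
    "null": "null",
    "cognitive": "cognitive_bias",
    "cognitive_bias": "cognitive_bias",
    "nonuniform": "stimulus_nonuniformity",
    "stimulus_nonuniformity": "stimulus_nonuniformity",
    "free": "free_similarity",
    "free_similarity": "free_similarity",
}


def truth_for_variant(variant: str, stimulus_set: StimulusSet | None = None) -> GroundTruth:
    """A canonical generating truth for each simulation variant.

    ``null`` uses the default unbiased agent; the other two are the matched
    mechanism scenarios (attractors near 17 and 212 degrees, and the warped
    space with the same mean-bias curve).
    """
    v = VARIANT_ALIASES[variant]
    if v == "null":
        return GroundTruth(variant="null", sigma=20.0, dprime=2.0)
    cognitive, nonuniform = make_fig3_scenarios(stimulus_set)
    return cognitive if v == "cognitive_bias" else nonuniform


def validate_trials(
    path,
    stimulus_set: StimulusSet | None = None,
    column_map: dict | None = None,
) -> TrialTable:
    """Load and validate a trial CSV, with per-row diagnostics on failure.

    ``column_map`` maps this package's column names to the names used in an
    externally archived dataset (e.g. ``{"cue": "CueIndex"}``); nothing is
    filtered silently -- any invariant violation raises with row numbers.
    """
    sset = stimulus_set if stimulus_set is not None else canonical_stimulus_set()
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    return TrialTable.from_frame(frame, sset)


def subsample_equal(
    tables: list[TrialTable], n: int, seed: int, replace: bool = False
) -> TrialTable:
    """Seeded equal-size subsample per subject, pooled.

    Without replacement, ``n`` must not exceed any table's size; with
    replacement any ``n`` works (the bootstrap setting).  Subject labels are
    retained in ``session_id``.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for t in tables:
        if replace:
            idx = rng.integers(0, t.n_trials, n)
        else:
            if n > t.n_trials:
                raise ValueError(
                    f"cannot draw {n} trials without replacement from a table of {t.n_trials}"
                )
            idx = rng.permutation(t.n_trials)[:n]
        parts.append(t.subset(idx))
    return TrialTable.concatenate(parts)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``input_paths`` (CSV files, one per subject) or ``simulate``
    (variant name) must be set.  Every stochastic step derives its seed from
    ``seed`` and records it in the outputs.
    """

    out_dir: str
    input_paths: list[str] = field(default_factory=list)
    simulate: str | None = None
    n_trials: int = 25000
    seed: int = 0
    mixture: bool = True
    crossing_bootstrap: int = 0
    tccv_variants: list[str] = field(default_factory=lambda: ["null", "nonuniform", "cognitive"])
    restarts: int = 1
    bootstrap_B: int = 0
    derive_mucs: bool = True
    mucs_samples: int = 64

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded,
        so identical analyses hash identically wherever they are written)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stamp(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def fit_to_dict(result) -> dict:
    model = result.model
    params: dict = {"dprime": model.dprime}
    if model.sigma is not None:
        params["sigma"] = model.sigma
    if model.offsets is not None:
        params["offsets"] = model.offsets.tolist()
    if model.distances is not None:
        params["distances"] = model.distances.tolist()
    if model.similarity_values is not None:
        params["similarity_matrix"] = [
            [None if np.isnan(v) else v for v in row] for row in model.similarity_values
        ]
    return {
        "variant": model.variant,
        "k": result.n_params,
        "effective_k": result.effective_n_params,
        "n": result.n_trials,
        "nll": result.nll,
        "aic": result.aic,
        "bic": result.bic,
        "params": params,
        "converged": result.converged,
        "n_restarts": result.n_restarts,
        "seed": result.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write JSON artifacts to out_dir.

    Returns the report dict (also written as ``report.json``).  Inputs are
    never mutated; all filtering/subsampling is logged with counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline_stages(config, out)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run_pipeline_stages(config: RunConfig, out: Path) -> dict:
    report: dict = {**_stamp(config), "stages": []}

    if config.input_paths:
        tables = [validate_trials(p) for p in config.input_paths]
        trials = TrialTable.concatenate(tables) if len(tables) > 1 else tables[0]
        logger.info("loaded %d table(s), %d trials", len(tables), trials.n_trials)
    elif config.simulate is not None:
        truth = truth_for_variant(config.simulate)
        sset = canonical_stimulus_set()
        trials = generate_trials(truth, sset, config.n_trials, seed=config.seed)
        tables = [trials]
        logger.info("simulated %d trials from %s", trials.n_trials, config.simulate)
    else:
        raise ValueError("config must set input_paths or simulate")
    report["n_trials"] = trials.n_trials
    report["accuracy"] = trials.accuracy()
    # per-subject bookkeeping (completed and incorrect trials)
    labels = np.unique(trials.session_id)
    incorrect = ~trials.correct
    per_subject = {
        str(s): {
            "completed": int(np.sum(trials.session_id == s)),
            "incorrect": int(np.sum(incorrect[trials.session_id == s])),
        }
        for s in labels
    }
    report["subjects"] = per_subject
    for s, c in per_subject.items():
        logger.info("subject %s: %d completed, %d incorrect", s, c["completed"], c["incorrect"])

    if config.mixture:
        mix = analyze_mixture(trials, n_boot=config.crossing_bootstrap, seed=config.seed + 1)
        payload = {**_stamp(config), **mix.to_dict()}
        _json_dump(payload, out / "mixture.json")
        report["stages"].append("mixture")
        report["mixture"] = {
            "significant_attractors": [c.angle for c in mix.significant_attractors()],
            "n_crossings": len(mix.crossings),
        }

    results = {}
    for alias in config.tccv_variants:
        variant = VARIANT_ALIASES[alias]
        res = fit(variant, trials, restarts=config.restarts, seed=config.seed + 2)
        results[variant] = res
        logger.info("fit %s: nll=%.1f bic=%.1f", variant, res.nll, res.bic)
    if results:
        _json_dump(
            {**_stamp(config), "fits": {v: fit_to_dict(r) for v, r in results.items()}},
            out / "fits.json",
        )
        report["stages"].append("tccv")
        report["bic"] = {v: r.bic for v, r in results.items()}
        report["best_variant"] = min(results, key=lambda v: results[v].bic)

    if config.bootstrap_B > 0:
        comp = bootstrap_compare(
            tables, B=config.bootstrap_B, seed=config.seed + 3, restarts=config.restarts
        )
        _json_dump(
            {
                **_stamp(config),
                "variants": comp["variants"],
                "bic": comp["bic"].tolist(),
                "wins": comp["wins"],
                "n_draw": comp["n_draw"],
            },
            out / "compare.json",
        )
        report["stages"].append("bootstrap_compare")
        report["bootstrap_wins"] = comp["wins"]

    if config.derive_mucs and "stimulus_nonuniformity" in results:
        res = results["stimulus_nonuniformity"]
        if res.converged:
            space_map = derive_map(res, cieluv_hues=trials.stimulus_set.hue_angles)
            _json_dump(
                {
                    **_stamp(config),
                    "cieluv_hues": space_map.cieluv_hues.tolist(),
                    "mucs_hues": space_map.mucs_hues.tolist(),
                    "uniform_samples_cieluv": sample_uniform_mucs(
                        space_map, config.mucs_samples
                    ).tolist(),
                },
                out / "mucs.json",
            )
            report["stages"].append("mucs")

    _json_dump(report, out / "report.json")
    return report
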