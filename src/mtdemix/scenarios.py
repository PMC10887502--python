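"""Canned validation scenarios: seeded synthetic mixtures run end to end.

These presets pin the study conditions the package is validated under:
two-person mixtures with minor contributions between 5% and 50%, the six
standard mixing ratios (1:1, 1:3, 3:1 two-person; 1:1:1, 1:3:3, 3:3:1
three-person), and 20,000 read fragments per mixture (~200x mitogenome
coverage). Contributor pairs are drawn from distinct clades of the bundled
mini-tree, differing at five or more diagnostic SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .deconvolve import DeconvolveConfig, DeconvolutionResult, deconvolute, deconvolute_with_knowns
from .fileio import read_fastq_pair
from .preprocess import PreprocessConfig, preprocess_pairs
from .simdata import ContributorSpec, MixtureScenario, make_mixture

__all__ = [
    "EndToEndRun",
    "run_end_to_end",
    "detection_panel",
    "ratio_panel",
    "proportion_panel",
    "exact_detection_rate",
    "adjacent_detection_rate",
    "DEFAULT_TOTAL_FRAGMENTS",
]

DEFAULT_TOTAL_FRAGMENTS = 20_000

# two-person detection panel: (major, minor, ratio); minors cycle through
# 5%, 10%, 25% and 50% contributions
DETECTION_PAIRS: list[tuple[str, str, tuple[int, int]]] = [
    ("L0a", "U5a", (19, 1)),
    ("L1c2", "J1", (9, 1)),
    ("B2o", "T2", (3, 1)),
    ("K", "L0a", (1, 1)),
    ("J1", "U5a", (19, 1)),
    ("T2", "L1c2", (9, 1)),
    ("U5a", "B2o", (3, 1)),
    ("L0a", "K", (1, 1)),
    ("T2", "L0a", (19, 1)),
    ("K", "J1", (9, 1)),
]

# one mixture per standard ratio (15 contributor slots)
RATIO_PANEL: list[tuple[tuple[str, ...], tuple[int, ...]]] = [
    (("L0a", "U5a"), (1, 1)),
    (("L1c2", "J1"), (1, 3)),
    (("B2o", "K"), (3, 1)),
    (("L0a", "U5a", "J1"), (1, 1, 1)),
    (("L1c2", "T2", "K"), (1, 3, 3)),
    (("B2o", "J1", "L0a"), (3, 3, 1)),
]


@dataclass
class EndToEndRun:
    scenario: MixtureScenario
    result: DeconvolutionResult
    metrics: dict


def run_end_to_end(
    workdir: str | Path,
    contributors: list[ContributorSpec],
    ratio: tuple[int, ...],
    total: int,
    seed: int,
    numt_count: int = 0,
    with_knowns: bool = False,
    config: DeconvolveConfig | None = None,
) -> EndToEndRun:
    """Simulate one mixture and run the full pipeline on it."""
    scenario = make_mixture(workdir, contributors, ratio, total, seed, numt_count=numt_count)
    pairs = read_fastq_pair(scenario.r1, scenario.r2)
    prep = preprocess_pairs(
        pairs, scenario.primers, scenario.ref, scenario.nuclear_seq, PreprocessConfig()
    )
    if with_knowns:
        result = deconvolute_with_knowns(
            prep.fragments, scenario.tree, scenario.known_haplotypes(), scenario.ref, config
        )
    else:
        result = deconvolute(prep.fragments, scenario.tree, scenario.ref, config)
    return EndToEndRun(scenario=scenario, result=result, metrics=prep.metrics)


def _panel_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def detection_panel(
    workdir: str | Path, seed: int, total: int = DEFAULT_TOTAL_FRAGMENTS
) -> list[EndToEndRun]:
    """Ten seeded two-person mixtures, minor contribution 5-50%."""
    seeds = _panel_seeds(seed, len(DETECTION_PAIRS))
    runs = []
    for i, (major, minor, ratio) in enumerate(DETECTION_PAIRS):
        runs.append(
            run_end_to_end(
                Path(workdir) / f"det{i:02d}",
                [ContributorSpec(major), ContributorSpec(minor)],
                ratio,
                total,
                seeds[i],
            )
        )
    return runs


def ratio_panel(
    workdir: str | Path, seed: int, total: int = DEFAULT_TOTAL_FRAGMENTS
) -> list[EndToEndRun]:
    """One mixture per standard two- and three-person mixing ratio."""
    seeds = _panel_seeds(seed + 1, len(RATIO_PANEL))
    runs = []
    for i, (names, ratio) in enumerate(RATIO_PANEL):
        runs.append(
            run_end_to_end(
                Path(workdir) / f"ratio{i:02d}",
                [ContributorSpec(n) for n in names],
                ratio,
                total,
                seeds[i],
            )
        )
    return runs


def proportion_panel(
    workdir: str | Path, seed: int, n_mixtures: int = 20, total: int = DEFAULT_TOTAL_FRAGMENTS
) -> list[EndToEndRun]:
    """Seeded two-person mixtures for proportion-recovery measurement."""
    seeds = _panel_seeds(seed + 2, n_mixtures)
    runs = []
    for i in range(n_mixtures):
        major, minor, ratio = DETECTION_PAIRS[i % len(DETECTION_PAIRS)]
        runs.append(
            run_end_to_end(
                Path(workdir) / f"prop{i:02d}",
                [ContributorSpec(major), ContributorSpec(minor)],
                ratio,
                total,
                seeds[i],
            )
        )
    return runs


def exact_detection_rate(runs: list[EndToEndRun]) -> float:
    """Percent of true contributors whose exact haplogroup name is reported."""
    hits = slots = 0
    for run in runs:
        reported = set(run.result.contributor_names())
        for c in run.result.contributors:
            reported.update(c.aliases)
        for hg in run.scenario.truth:
            slots += 1
            hits += hg in reported
    return 100.0 * hits / slots


def adjacent_detection_rate(runs: list[EndToEndRun]) -> float:
    """Percent of true contributors reported at the exact node or a direct
    parent/child of it."""
    hits = slots = 0
    for run in runs:
        tree = run.scenario.tree
        reported = set(run.result.contributor_names())
        for c in run.result.contributors:
            reported.update(c.aliases)
        for hg in run.scenario.truth:
            slots += 1
            hits += bool(tree.neighbors(hg) & reported)
    return 100.0 * hits / slots


def mean_abs_proportion_error(runs: list[EndToEndRun]) -> float:
    """Mean |estimated - true| proportion over all true contributors."""
    errors = []
    for run in runs:
        for hg, true_p in run.scenario.truth.items():
            est = run.result.proportion_of(hg)
            errors.append(abs((est if est is not None else 0.0) - true_p))
    return float(np.mean(errors))
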