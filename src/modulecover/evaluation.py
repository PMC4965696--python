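"""Jaccard-overlap robustness and gold-standard validation analyses.

Robustness of an extraction result is assessed by comparing the largest
solution found on randomly perturbed copies of the network against the
largest solution on the original network, via the Jaccard similarity of
their gene sets:

    J(S_perturbed, S_unperturbed) = |S_p ∩ S_u| / |S_p ∪ S_u|

With a gold-standard gene set S_gold available, J(S_perturbed, S_gold) and
the baseline J(S_unperturbed, S_gold) measure solution quality instead.
Each perturbation level gets ``n_per_level`` independently perturbed
replicate networks; replicate seeds derive from a stable hash of
(master seed, strategy, level, replicate) so that adding levels does not
shift other replicates' random streams.

Note the indicator matrices are never relabeled: under node-label
permutation a gene's activity follows its label to the label's new
topological position, which is precisely what makes the strategy
informative.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np

from .datasets import DatasetCollection
from .enrichment import EMPTY_PATHWAY, ExtractionConfig, Pathway, run_extraction
from .network import InteractionNetwork
from .perturbation import perturb

logger = logging.getLogger(__name__)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard similarity |a ∩ b| / |a ∪ b|; two empty sets count as equal."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        logger.warning("Jaccard of two empty sets; returning 1.0 (equal sets)")
        return 1.0
    return len(sa & sb) / len(union)


def largest_solution(solutions: Sequence[Pathway]) -> Pathway:
    """The solution with the most nodes; ties break on the lexicographically
    smallest sorted node tuple.  An empty list yields the empty pathway."""
    if not solutions:
        return EMPTY_PATHWAY
    return min(solutions, key=Pathway.sort_key)


def replicate_seed(master_seed: int, strategy: str, level: float, replicate: int) -> int:
    """Stable per-replicate seed below 2^31."""
    key = f"{master_seed}|{strategy}|{level:g}|{replicate}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class ReplicateRecord:
    level: float
    replicate: int
    seed: int
    jaccard: float
    solution_size: int


@dataclass
class RobustnessResult:
    """Per-level Jaccard overlaps of perturbed vs unperturbed solutions."""

    strategy: str
    levels: list[float]
    n_per_level: int
    master_seed: int
    baseline: Pathway
    records: list[ReplicateRecord] = field(default_factory=list)

    def values_at(self, level: float) -> list[float]:
        return [r.jaccard for r in self.records if r.level == level]


@dataclass
class ValidationResult(RobustnessResult):
    """Per-level Jaccard overlaps of perturbed solutions with a gold set."""

    gold: frozenset[str] = frozenset()
    baseline_jaccard: float = float("nan")


def _run_batch(
    network: InteractionNetwork,
    datasets: DatasetCollection,
    config: ExtractionConfig,
    strategy: str,
    levels: Sequence[float],
    n_per_level: int,
    master_seed: int,
    score,
    positive: Iterable[str] = (),
) -> list[ReplicateRecord]:
    records = []
    for level in levels:
        for rep in range(n_per_level):
            seed = replicate_seed(master_seed, strategy, level, rep)
            perturbed = perturb(network, strategy, level, seed)
            try:
                sols = run_extraction(perturbed.network, datasets, config, positive)
            except Exception as exc:  # noqa: BLE001 — a failed replicate is data
                logger.warning(
                    "extraction failed on %s level %g replicate %d: %s",
                    strategy,
                    level,
                    rep,
                    exc,
                )
                sols = []
            top = largest_solution(sols)
            records.append(
                ReplicateRecord(level, rep, seed, score(top), top.size)
            )
    return records


def robustness_analysis(
    network: InteractionNetwork,
    datasets: DatasetCollection,
    config: ExtractionConfig,
    strategy: str,
    levels: Sequence[float],
    n_per_level: int,
    master_seed: int,
    positive: Iterable[str] = (),
) -> RobustnessResult:
    """Extract once on the unperturbed network, then on ``n_per_level``
    perturbed replicates per level, recording J(top_perturbed, top_unperturbed)."""
    if not levels:
        raise ValueError("levels must be non-empty")
    baseline = largest_solution(run_extraction(network, datasets, config, positive))
    result = RobustnessResult(strategy, list(levels), n_per_level, master_seed, baseline)
    result.records = _run_batch(
        network,
        datasets,
        config,
        strategy,
        levels,
        n_per_level,
        master_seed,
        score=lambda top: jaccard(top.nodes, baseline.nodes),
        positive=positive,
    )
    return result


def validation_analysis(
    network: InteractionNetwork,
    datasets: DatasetCollection,
    config: ExtractionConfig,
    strategy: str,
    levels: Sequence[float],
    n_per_level: int,
    gold: Iterable[str],
    master_seed: int,
    positive: Iterable[str] = (),
) -> ValidationResult:
    """Like :func:`robustness_analysis` but scoring each replicate's top
    solution against a gold-standard gene set (exception nodes included —
    a disease gene recovered as an exception node counts)."""
    gold_set = frozenset(gold)
    if not gold_set:
        raise ValueError("gold standard set must be non-empty")
    if not levels:
        raise ValueError("levels must be non-empty")
    baseline = largest_solution(run_extraction(network, datasets, config, positive))
    result = ValidationResult(
        strategy,
        list(levels),
        n_per_level,
        master_seed,
        baseline,
        gold=gold_set,
        baseline_jaccard=jaccard(baseline.nodes, gold_set),
    )
    result.records = _run_batch(
        network,
        datasets,
        config,
        strategy,
        levels,
        n_per_level,
        master_seed,
        score=lambda top: jaccard(top.nodes, gold_set),
        positive=positive,
    )
    return result


@dataclass(frozen=True)
class LevelSummary:
    level: float
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float


def summarize(result: RobustnessResult) -> list[LevelSummary]:
    """Per-level mean / sd / median / min / max of the Jaccard values."""
    out = []
    for level in result.levels:
        vals = np.asarray(result.values_at(level), dtype=float)
        if vals.size == 0:
            raise ValueError(f"no values recorded at level {level}")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.append(
            LevelSummary(
                level,
                int(vals.size),
                float(vals.mean()),
                sd,
                float(np.median(vals)),
                float(vals.min()),
                float(vals.max()),
            )
        )
    return out


def _open_maybe(dest: Union[str, Path, IO[str]]):
    if hasattr(dest, "write"):
        return dest, False
    return open(dest, "w"), True


def write_records_tsv(result: RobustnessResult, dest: Union[str, Path, IO[str]]) -> None:
    fh, close = _open_maybe(dest)
    try:
        fh.write("level\treplicate\tseed\tjaccard\tsolution_size\n")
        for r in result.records:
            fh.write(f"{r.level:g}\t{r.replicate}\t{r.seed}\t{r.jaccard:.6f}\t{r.solution_size}\n")
    finally:
        if close:
            fh.close()


def write_summary_tsv(result: RobustnessResult, dest: Union[str, Path, IO[str]]) -> None:
    fh, close = _open_maybe(dest)
    try:
        fh.write("level\tn\tmean\tsd\tmedian\tmin\tmax\n")
        for s in summarize(result):
            fh.write(
                f"{s.level:g}\t{s.n}\t{s.mean:.6f}\t{s.sd:.6f}\t"
                f"{s.median:.6f}\t{s.min:.6f}\t{s.max:.6f}\n"
            )
    finally:
        if close:
            fh.close()


def plot_boxes(result: RobustnessResult, dest: Union[str, Path]) -> None:
    """Box plot of Jaccard values per perturbation level (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [result.values_at(level) for level in result.levels]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=[f"{lv:g}%" for lv in result.levels])
    ax.set_xlabel(f"perturbation level ({result.strategy})")
    ax.set_ylabel("Jaccard overlap")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(dest, dpi=120)
    plt.close(fig)
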