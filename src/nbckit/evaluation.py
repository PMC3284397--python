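"""Score classifier output against simulation truth, break novel-source
results down by predominant match, and compare two classifiers.

All rank-level comparisons go through :func:`nbckit.taxonomy.agree_at_rank`,
so lineage gaps (UNKNOWN labels) and unclassified reads land in an explicit
*indeterminate* category and are excluded from accuracy denominators — a
gap is reported, never silently counted as an error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .kmer_core import ClassificationResult
from .taxonomy import RANKS, TaxonomyTable, agree_at_rank

__all__ = [
    "RankAccuracy",
    "RankAccuracyReport",
    "NoveltyBreakdownRow",
    "AgreementReport",
    "rank_accuracy",
    "organism_mean_accuracy",
    "predominant_match_breakdown",
    "compare_assignments",
    "write_predictions",
    "load_predictions",
    "load_truth",
    "EvaluationError",
    "PREDICTION_COLUMNS",
]

PREDICTION_COLUMNS = ("read_id", "best_taxon", "best_score", "runner_up", "margin")

#: Default ranks for cross-classifier agreement.
AGREEMENT_RANKS = ("species", "genus", "phylum")


class EvaluationError(ValueError):
    pass


@dataclass
class RankAccuracy:
    """Per-rank tally; ``accuracy = n_correct / n_evaluable``."""

    rank: str
    n_evaluable: int
    n_correct: int
    n_indeterminate: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_evaluable if self.n_evaluable else float("nan")


@dataclass
class RankAccuracyReport:
    per_rank: dict = field(default_factory=dict)  # rank -> RankAccuracy
    n_reads: int = 0

    def accuracy(self, rank: str) -> float:
        return self.per_rank[rank].accuracy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": ra.rank,
                    "n_evaluable": ra.n_evaluable,
                    "n_correct": ra.n_correct,
                    "n_indeterminate": ra.n_indeterminate,
                    "accuracy": ra.accuracy,
                }
                for ra in self.per_rank.values()
            ]
        )


@dataclass
class NoveltyBreakdownRow:
    """Modal prediction among all reads simulated from one source organism.

    ``confident`` is True when the modal fraction strictly exceeds the
    threshold (default 0.40) — a source whose reads scatter across many
    taxa, or sink into a long-genome attractor, is not confidently placed.
    """

    source_organism: str
    n_reads: int
    predominant_match: Optional[str]
    fraction: float
    confident: bool


@dataclass
class AgreementReport:
    """Per-rank match/mismatch/indeterminate fractions over shared reads."""

    per_rank: dict = field(default_factory=dict)  # rank -> dict of 3 fractions
    n_shared: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rank": r, **fr} for r, fr in self.per_rank.items()]
        )


def _as_prediction_map(predictions) -> dict[str, Optional[str]]:
    """Accept ClassificationResults, a mapping, or a predictions frame."""
    if isinstance(predictions, Mapping):
        return dict(predictions)
    if isinstance(predictions, pd.DataFrame):
        return {
            row.read_id: (row.best_taxon if row.best_taxon else None)
            for row in predictions.itertuples()
        }
    out: dict[str, Optional[str]] = {}
    for item in predictions:
        if isinstance(item, ClassificationResult):
            out[item.read_id] = item.best_taxon
        else:
            rid, taxon = item
            out[rid] = taxon or None
    return out


def rank_accuracy(
    predictions,
    truth: Mapping[str, str],
    taxonomy: TaxonomyTable,
    ranks: Sequence[str] = RANKS,
) -> RankAccuracyReport:
    """Fraction of reads whose prediction matches truth at each rank.

    ``truth`` maps read_id -> true source taxon. A read is correct at a
    rank iff predicted and true lineages agree there; reads that are
    unclassified, or whose comparison is indeterminate (UNKNOWN at that
    rank), are excluded from the denominator and counted separately.
    """
    preds = _as_prediction_map(predictions)
    missing = [rid for rid in preds if rid not in truth]
    if missing:
        raise EvaluationError(
            f"{len(missing)} predicted read(s) absent from truth, e.g. {missing[:3]}"
        )
    report = RankAccuracyReport(n_reads=len(preds))
    for rank in ranks:
        n_correct = n_indet = n_eval = 0
        for rid, pred_taxon in preds.items():
            if pred_taxon is None:
                n_indet += 1
                continue
            verdict = agree_at_rank(taxonomy, pred_taxon, truth[rid], rank)
            if verdict == "indeterminate":
                n_indet += 1
            else:
                n_eval += 1
                if verdict == "match":
                    n_correct += 1
        report.per_rank[rank] = RankAccuracy(rank, n_eval, n_correct, n_indet)
    return report


def organism_mean_accuracy(
    predictions,
    truth: Mapping[str, str],
    sources: Mapping[str, str],
    taxonomy: TaxonomyTable,
    ranks: Sequence[str] = RANKS,
) -> dict[str, float]:
    """Per-rank accuracy averaged over source organisms instead of reads.

    ``sources`` maps read_id -> source organism. Each organism's per-read
    accuracy is computed first, then organisms are averaged with equal
    weight; organisms with no evaluable read at a rank are skipped. This
    is the "on average over organisms" convention, complementing the
    per-read convention of :func:`rank_accuracy`.
    """
    preds = _as_prediction_map(predictions)
    by_org: dict[str, dict[str, Optional[str]]] = {}
    for rid, taxon in preds.items():
        by_org.setdefault(sources[rid], {})[rid] = taxon
    out: dict[str, float] = {}
    for rank in ranks:
        accs = []
        for org, org_preds in by_org.items():
            ra = rank_accuracy(org_preds, truth, taxonomy, ranks=[rank]).per_rank[rank]
            if ra.n_evaluable:
                accs.append(ra.accuracy)
        out[rank] = sum(accs) / len(accs) if accs else float("nan")
    return out


def predominant_match_breakdown(
    predictions,
    sources: Mapping[str, str],
    threshold: float = 0.40,
) -> list[NoveltyBreakdownRow]:
    """Per source organism: the modal predicted taxon and its read fraction.

    ``confident`` requires the modal fraction to *strictly* exceed the
    threshold. Modal ties break lexicographically; unclassified reads
    count in the denominator but never become the mode.
    """
    preds = _as_prediction_map(predictions)
    by_org: dict[str, list[Optional[str]]] = {}
    for rid, taxon in preds.items():
        if rid not in sources:
            raise EvaluationError(f"read {rid!r} has no source organism in truth")
        by_org.setdefault(sources[rid], []).append(taxon)
    rows = []
    for org in sorted(by_org):
        assigned = by_org[org]
        tally = Counter(t for t in assigned if t is not None)
        if tally:
            best_count = max(tally.values())
            modal = min(t for t, c in tally.items() if c == best_count)
            fraction = best_count / len(assigned)
        else:
            modal, fraction = None, 0.0
        rows.append(
            NoveltyBreakdownRow(
                source_organism=org,
                n_reads=len(assigned),
                predominant_match=modal,
                fraction=fraction,
                confident=fraction > threshold,
            )
        )
    return rows


def compare_assignments(
    predictions_a,
    predictions_b,
    taxonomy: TaxonomyTable,
    ranks: Sequence[str] = AGREEMENT_RANKS,
) -> AgreementReport:
    """Rank-level agreement between two classifiers on shared reads.

    Works over the intersection of read ids; symmetric in its arguments.
    A read either classifier leaves unclassified, or whose lineages are
    UNKNOWN at a rank, is indeterminate there. The three fractions sum
    to 1 per rank.
    """
    a = _as_prediction_map(predictions_a)
    b = _as_prediction_map(predictions_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise EvaluationError("the two prediction sets share no read ids")
    report = AgreementReport(n_shared=len(shared))
    for rank in ranks:
        tally = {"match": 0, "mismatch": 0, "indeterminate": 0}
        for rid in shared:
            ta, tb = a[rid], b[rid]
            if ta is None or tb is None:
                tally["indeterminate"] += 1
            else:
                tally[agree_at_rank(taxonomy, ta, tb, rank)] += 1
        report.per_rank[rank] = {k: v / len(shared) for k, v in tally.items()}
    return report


def write_predictions(results: Iterable[ClassificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.best_taxon or "",
                        "" if r.best_score is None else repr(r.best_score),
                        r.runner_up_taxon or "",
                        "" if r.margin is None else repr(r.margin),
                    ]
                )
                + "\n"
            )


def load_predictions(path) -> dict[str, Optional[str]]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if "read_id" not in df.columns or "best_taxon" not in df.columns:
        raise EvaluationError(f"{path} is not a predictions TSV")
    return {row.read_id: (row.best_taxon or None) for row in df.itertuples()}


def load_truth(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype={"read_id": str}, keep_default_na=False)
    if "read_id" not in df.columns or "source_taxon" not in df.columns:
        raise EvaluationError(f"{path} is not a truth TSV")
    return df
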