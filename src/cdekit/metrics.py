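"""Reuse and integration statistics for CDE extraction corpora.

Given per-document lists of extracted CDE occurrences (ids or canonical
signatures), grouped by source (a hospital, a resource set), computes the
counts and percentages used to quantify metadata reuse:

* **reuse rate** — (n_total − n_unique) / n_total × 100: the share of
  extraction events that were repeats of an already-seen element;
* **capture share** — n_captured / denominator × 100: how much of the
  element pool composites absorbed (both the unique-pool and the
  total-extracted denominators occur in practice, so it is explicit);
* **representation count** — n_ccde + n_free: how many registry items
  (composites plus uncaptured atomics) suffice to represent the corpus;
* **integration reuse ratio** — (n_total − n_ccde_unique − n_unique) /
  n_total × 100: the reduction achieved once unique elements are further
  folded into composites.

All percentages are rounded half-up to one decimal, the convention the
source tables use (banker's rounding would disagree at .x5 boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

__all__ = [
    "MetricsError",
    "Document",
    "CompositeAssignment",
    "Group",
    "ExtractionCorpus",
    "GroupMetrics",
    "IntegrationReport",
    "round_half_up",
    "reuse_rate",
    "integration_reuse_ratio",
    "capture_share",
    "representation_count",
    "deduplicate",
    "DedupResult",
    "metrics_report",
    "metrics_from_counts",
]


class MetricsError(ValueError):
    """Invalid corpus or count arguments."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Formulas
# ---------------------------------------------------------------------------


def reuse_rate(n_total: int, n_unique: int) -> float:
    """Percent of occurrences that repeat an already-extracted element."""
    if n_total <= 0:
        raise MetricsError("n_total must be positive")
    if not (0 < n_unique <= n_total):
        raise MetricsError("n_unique must satisfy 0 < n_unique <= n_total")
    return round_half_up((n_total - n_unique) / n_total * 100.0)


def integration_reuse_ratio(n_total: int, n_ccde_unique: int, n_unique: int) -> float:
    """Percent reduction once unique elements fold into composites."""
    if n_total <= 0:
        raise MetricsError("n_total must be positive")
    if n_ccde_unique < 0 or n_unique < 0 or n_ccde_unique + n_unique > n_total:
        raise MetricsError("require 0 <= n_ccde_unique + n_unique <= n_total")
    return round_half_up((n_total - n_ccde_unique - n_unique) / n_total * 100.0)


def capture_share(n_captured: int, denominator: int) -> float:
    """Percent of the chosen pool absorbed into composites."""
    if denominator <= 0:
        raise MetricsError("denominator must be positive")
    if not (0 <= n_captured <= denominator):
        raise MetricsError("require 0 <= n_captured <= denominator")
    return round_half_up(n_captured / denominator * 100.0)


def representation_count(n_ccde: int, n_free: int) -> int:
    """Composites plus uncaptured atomics needed to represent the corpus."""
    if n_ccde < 0 or n_free < 0:
        raise MetricsError("counts must be non-negative")
    return n_ccde + n_free


# ---------------------------------------------------------------------------
# Corpus model
# ---------------------------------------------------------------------------


@dataclass
class Document:
    name: str
    occurrences: list = field(default_factory=list)  # ids or signatures


@dataclass
class CompositeAssignment:
    id: str
    members: list = field(default_factory=list)  # occurrence signatures


@dataclass
class Group:
    name: str
    documents: list = field(default_factory=list)
    composites: list = field(default_factory=list)


@dataclass
class ExtractionCorpus:
    groups: list = field(default_factory=list)

    def validate(self) -> None:
        if not self.groups:
            raise MetricsError("empty corpus")
        for g in self.groups:
            pool = set()
            for d in g.documents:
                for occ in d.occurrences:
                    if not str(occ).strip():
                        raise MetricsError(f"{g.name}/{d.name}: empty occurrence")
                    pool.add(occ)
            for c in g.composites:
                missing = [m for m in c.members if m not in pool]
                if missing:
                    raise MetricsError(
                        f"{g.name}: composite {c.id} members {missing} absent from corpus"
                    )

    @classmethod
    def from_dict(cls, payload: dict) -> "ExtractionCorpus":
        corpus = cls(
            groups=[
                Group(
                    name=g["name"],
                    documents=[
                        Document(d["name"], list(d.get("occurrences", ())))
                        for d in g.get("documents", ())
                    ],
                    composites=[
                        CompositeAssignment(c["id"], list(c.get("members", ())))
                        for c in g.get("composites", ())
                    ],
                )
                for g in payload.get("groups", ())
            ]
        )
        corpus.validate()
        return corpus

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "name": g.name,
                    "documents": [
                        {"name": d.name, "occurrences": list(d.occurrences)}
                        for d in g.documents
                    ],
                    "composites": [
                        {"id": c.id, "members": list(c.members)} for c in g.composites
                    ],
                }
                for g in self.groups
            ]
        }


@dataclass(frozen=True)
class DedupResult:
    n_total: int
    n_unique: int
    signatures: frozenset
    reused: frozenset  # signatures occurring in >= 2 documents


def deduplicate(corpus: ExtractionCorpus, scope: Optional[str] = None) -> DedupResult:
    """Collapse occurrences to unique signatures within a group or overall.

    ``scope`` names a group, or None for the pooled corpus.  Also reports
    the signatures appearing in at least two documents (the reused set).
    """
    if scope is None:
        documents = [d for g in corpus.groups for d in g.documents]
    else:
        matches = [g for g in corpus.groups if g.name == scope]
        if not matches:
            raise MetricsError(f"unknown group: {scope!r}")
        documents = list(matches[0].documents)
    if not documents:
        raise MetricsError("no documents in scope")
    n_total = 0
    doc_count: dict = {}
    for d in documents:
        n_total += len(d.occurrences)
        for sig in set(d.occurrences):
            doc_count[sig] = doc_count.get(sig, 0) + 1
    return DedupResult(
        n_total=n_total,
        n_unique=len(doc_count),
        signatures=frozenset(doc_count),
        reused=frozenset(s for s, c in doc_count.items() if c >= 2),
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class GroupMetrics:
    name: str
    n_total: int
    n_unique: int
    n_ccde: int
    captured_total: int
    captured_unique: int
    n_free: int
    representation: int
    reuse_rate: float
    capture_share_unique: float
    capture_share_total: float
    representation_efficiency: float
    integration_reuse_ratio: float

    def to_row(self) -> dict:
        """Column letters follow the source table's footnote scheme:
        a extracted, b composites, c captured, d free, e representation,
        f unique, g reuse rate."""
        return {
            "group": self.name,
            "a_cde_extracted": self.n_total,
            "b_ccde": self.n_ccde,
            "c_acde_captured": self.captured_unique,
            "d_acde_free": self.n_free,
            "e_ccde_plus_acde": self.representation,
            "f_unique_cde": self.n_unique,
            "g_reuse_rate_pct": self.reuse_rate,
            "capture_share_unique_pct": self.capture_share_unique,
            "capture_share_total_pct": self.capture_share_total,
            "representation_efficiency_pct": self.representation_efficiency,
            "integration_reuse_ratio_pct": self.integration_reuse_ratio,
        }


@dataclass
class IntegrationReport:
    groups: list = field(default_factory=list)
    overall: Optional[GroupMetrics] = None

    def to_rows(self) -> list:
        rows = [g.to_row() for g in self.groups]
        if self.overall is not None:
            rows.append(self.overall.to_row())
        return rows

    def to_dict(self) -> dict:
        return {"groups": self.to_rows()}


def _group_metrics(
    name: str,
    dedup: DedupResult,
    composites: Iterable[CompositeAssignment],
    occurrence_count: dict,
) -> GroupMetrics:
    composites = list(composites)
    captured_sigs = set()
    for c in composites:
        captured_sigs.update(c.members)
    captured_sigs &= dedup.signatures
    captured_unique = len(captured_sigs)
    captured_total = sum(occurrence_count.get(s, 0) for s in captured_sigs)
    n_ccde = len({c.id for c in composites})
    n_free = dedup.n_unique - captured_unique
    rep = representation_count(n_ccde, n_free)
    return GroupMetrics(
        name=name,
        n_total=dedup.n_total,
        n_unique=dedup.n_unique,
        n_ccde=n_ccde,
        captured_total=captured_total,
        captured_unique=captured_unique,
        n_free=n_free,
        representation=rep,
        reuse_rate=reuse_rate(dedup.n_total, dedup.n_unique),
        capture_share_unique=capture_share(captured_unique, dedup.n_unique),
        capture_share_total=capture_share(captured_total, dedup.n_total),
        representation_efficiency=capture_share(rep, dedup.n_total),
        integration_reuse_ratio=integration_reuse_ratio(
            dedup.n_total, n_ccde, dedup.n_unique
        ),
    )


def metrics_report(corpus: ExtractionCorpus) -> IntegrationReport:
    """Per-group and overall counts and percentages for a corpus.

    The overall row deduplicates over the pooled corpus, so its unique
    count can be below the sum of the per-group uniques; overall composite
    assignments are the union of group assignments keyed by composite id.
    """
    corpus.validate()
    report = IntegrationReport()
    for g in corpus.groups:
        dedup = deduplicate(corpus, g.name)
        occ_count: dict = {}
        for d in g.documents:
            for sig in d.occurrences:
                occ_count[sig] = occ_count.get(sig, 0) + 1
        report.groups.append(_group_metrics(g.name, dedup, g.composites, occ_count))
    overall_dedup = deduplicate(corpus, None)
    occ_count_all: dict = {}
    for g in corpus.groups:
        for d in g.documents:
            for sig in d.occurrences:
                occ_count_all[sig] = occ_count_all.get(sig, 0) + 1
    merged: dict = {}
    for g in corpus.groups:
        for c in g.composites:
            merged.setdefault(c.id, set()).update(c.members)
    overall_composites = [
        CompositeAssignment(cid, sorted(members)) for cid, members in sorted(merged.items())
    ]
    report.overall = _group_metrics(
        "overall", overall_dedup, overall_composites, occ_count_all
    )
    return report


def metrics_from_counts(counts: dict) -> dict:
    """Percentages straight from supplied counts (no occurrence lists).

    Recognized keys: n_total, n_unique, n_ccde_unique, n_captured,
    n_free, capture_denominator.  Only the quantities whose inputs are
    present are emitted, so printed summary tables can be checked without
    reconstructing the underlying documents.
    """
    out: dict = {}
    n_total = counts.get("n_total")
    n_unique = counts.get("n_unique")
    n_ccde = counts.get("n_ccde_unique")
    n_captured = counts.get("n_captured")
    n_free = counts.get("n_free")
    if n_total is not None and n_unique is not None:
        out["reuse_rate_pct"] = reuse_rate(n_total, n_unique)
        if n_ccde is not None:
            out["integration_reuse_ratio_pct"] = integration_reuse_ratio(
                n_total, n_ccde, n_unique
            )
    if n_captured is not None:
        denom = counts.get("capture_denominator")
        if denom is None:
            denom = n_unique if n_unique is not None else n_total
        if denom is not None:
            out["capture_share_pct"] = capture_share(n_captured, denom)
    if n_ccde is not None and n_free is not None:
        rep = representation_count(n_ccde, n_free)
        out["representation_count"] = rep
        if n_total is not None:
            out["representation_efficiency_pct"] = capture_share(rep, n_total)
    if not out:
        raise MetricsError("counts supply no computable metric")
    return out
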