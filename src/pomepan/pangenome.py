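"""Pan-genome presence/absence analysis.

A pan-gene's category is a pure function of how many of the N panel
cultivars carry it:

* ``present_in_all`` — all N;
* ``missing_from_one`` — exactly N-1;
* ``dispensable`` — between 2 and N-2;
* ``specific`` — exactly 1 (cultivar-specific).

The first two categories together form the *core* genome. Percentages are
reported half-away-from-zero to one decimal (two decimals below 1%), the
convention the published tables in this domain use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PAVMatrix
from .rounding import mean_rounded, percent

logger = logging.getLogger(__name__)

CATEGORIES = ("present_in_all", "missing_from_one", "dispensable", "specific")


@dataclass
class CoverageTable:
    """Per (gene, cultivar) exon coverage: total exon bases and bases covered
    at or above the caller's depth threshold."""

    frame: pd.DataFrame  # columns: gene_id, cultivar_id, exon_bases_total, exon_bases_covered

    def __post_init__(self) -> None:
        need = {"gene_id", "cultivar_id", "exon_bases_total", "exon_bases_covered"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"coverage table needs columns {sorted(need)}")
        bad = self.frame["exon_bases_covered"] > self.frame["exon_bases_total"]
        if bad.any():
            raise ValueError("covered bases exceed total exon bases")


def call_pav(
    cov: CoverageTable, min_depth: int = 2, lost_cutoff: float = 0.2
) -> PAVMatrix:
    """Call gene presence/absence from exon coverage fractions.

    A gene is absent in a cultivar when the fraction of its exon bases
    covered (at depth >= min_depth, already baked into the table) falls
    below ``lost_cutoff``. Genes absent everywhere are dropped with a
    warning — they carry no PAV information.

    ``min_depth`` is recorded for provenance; the depth gating itself
    happens upstream when the coverage table is computed.
    """
    frame = cov.frame
    if (frame["exon_bases_total"] == 0).any():
        genes = frame.loc[frame["exon_bases_total"] == 0, "gene_id"].unique()
        raise ValueError(f"gene(s) with zero exon bases: {list(genes[:5])}")
    frac = frame["exon_bases_covered"] / frame["exon_bases_total"]
    present = (
        frame.assign(present=(frac >= lost_cutoff).astype(int))
        .pivot(index="gene_id", columns="cultivar_id", values="present")
    )
    if present.isna().any().any():
        raise ValueError("coverage table is not a complete gene x cultivar grid")
    all_absent = present.sum(axis=1) == 0
    if all_absent.any():
        logger.warning(
            "dropping %d gene(s) absent in every cultivar", int(all_absent.sum())
        )
        present = present.loc[~all_absent]
    return PAVMatrix.from_frame(present)


@dataclass
class PavClassification:
    """Per-gene categories plus category counts and reported percentages."""

    per_gene: pd.DataFrame  # gene_id, n_present, category
    counts: dict[str, int]
    total: int
    n_cultivars: int

    @property
    def percentages(self) -> dict[str, float]:
        out = {c: percent(self.counts[c], self.total) for c in CATEGORIES}
        out["core"] = percent(
            self.counts["present_in_all"] + self.counts["missing_from_one"],
            self.total,
        )
        return out

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], n_cultivars: int
    ) -> "PavClassification":
        """Summary-only classification from published category counts."""
        total = sum(counts.values())
        empty = pd.DataFrame(columns=["gene_id", "n_present", "category"])
        return cls(empty, dict(counts), total, n_cultivars)


def categorize(n_present: np.ndarray, n_cultivars: int) -> np.ndarray:
    """Vector of category names from per-gene carrier counts."""
    n_present = np.asarray(n_present)
    if np.any(n_present < 1) or np.any(n_present > n_cultivars):
        raise ValueError("carrier counts outside 1..N")
    cats = np.where(
        n_present == n_cultivars,
        "present_in_all",
        np.where(
            n_present == n_cultivars - 1,
            "missing_from_one",
            np.where(n_present == 1, "specific", "dispensable"),
        ),
    )
    return cats


def classify_pav(pav: PAVMatrix) -> PavClassification:
    """Classify every pan-gene as core / dispensable / cultivar-specific."""
    if pav.n_cultivars < 3:
        raise ValueError("classification needs at least 3 cultivars")
    n_present = pav.n_present()
    cats = categorize(n_present, pav.n_cultivars)
    per_gene = pd.DataFrame(
        {"gene_id": pav.gene_ids, "n_present": n_present, "category": cats}
    )
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    assert sum(counts.values()) == pav.n_genes, "categories must partition genes"
    return PavClassification(per_gene, counts, pav.n_genes, pav.n_cultivars)


def combination_counts(pav: PAVMatrix, min_count: int = 1) -> pd.DataFrame:
    """Gene counts per distinct carrier set, sorted by descending count.

    ``min_count`` filters the returned table for display (the customary
    plotting cut is 5); pass 1 for the complete table. The complete table's
    counts always sum to the number of pan-genes.
    """
    carrier_sets = [
        tuple(c for c, p in zip(pav.cultivar_ids, row) if p)
        for row in pav.presence
    ]
    counter: dict[tuple[str, ...], int] = {}
    for cs in carrier_sets:
        counter[cs] = counter.get(cs, 0) + 1
    rows = sorted(
        counter.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0])
    )
    out = pd.DataFrame(
        {
            "carrier_set": [",".join(cs) for cs, _ in rows],
            "n_carriers": [len(cs) for cs, _ in rows],
            "n_genes": [n for _, n in rows],
        }
    )
    return out[out["n_genes"] >= min_count].reset_index(drop=True)


def accumulation_curve(
    pav: PAVMatrix,
    order: list[str] | None = None,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pan-gene count as cultivars are added one at a time.

    With an explicit ``order``, returns the cumulative union size after each
    added cultivar. Without one, averages over ``n_perm`` seeded random
    cultivar orderings and reports mean and standard deviation per step.
    The curve is monotone non-decreasing and ends at the pan-genome total.
    """
    if order is not None:
        unknown = set(order) - set(pav.cultivar_ids)
        if unknown:
            raise ValueError(f"unknown cultivar(s) in order: {sorted(unknown)}")
        counts = _cumulative_union(pav, list(order))
        return pd.DataFrame(
            {"k": np.arange(1, len(order) + 1), "pan_genes": counts}
        )
    rng = np.random.default_rng(seed)
    n = pav.n_cultivars
    all_counts = np.empty((n_perm, n), dtype=int)
    ids = list(pav.cultivar_ids)
    for i in range(n_perm):
        perm = [ids[j] for j in rng.permutation(n)]
        all_counts[i] = _cumulative_union(pav, perm)
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "pan_genes_mean": all_counts.mean(axis=0),
            "pan_genes_sd": all_counts.std(axis=0, ddof=1),
        }
    )


def _cumulative_union(pav: PAVMatrix, order: list[str]) -> np.ndarray:
    idx = [pav.cultivar_ids.index(c) for c in order]
    cum = np.logical_or.accumulate(pav.presence[:, idx], axis=1)
    return cum.sum(axis=0)


def subset_representation(pav: PAVMatrix, subset: list[str]) -> tuple[int, float]:
    """How much of the pan-genome a cultivar subset carries.

    Returns (number of pan-genes present in the union of the subset's
    columns, that count as a reported percentage of the pan total).
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = set(subset) - set(pav.cultivar_ids)
    if unknown:
        raise ValueError(f"unknown cultivar(s): {sorted(unknown)}")
    idx = [pav.cultivar_ids.index(c) for c in subset]
    n_union = int(pav.presence[:, idx].any(axis=1).sum())
    return n_union, percent(n_union, pav.n_genes)


def genes_added(pav: PAVMatrix, base_subset: list[str], new_cultivar: str) -> int:
    """Pan-genes a cultivar adds on top of an existing subset."""
    with_new, _ = subset_representation(pav, list(base_subset) + [new_cultivar])
    base, _ = subset_representation(pav, list(base_subset))
    return with_new - base


def contig_summary_from_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Mean contig length per cultivar from (n_contigs, total_bp) pairs.

    Means are rounded to the nearest integer half away from zero; a cultivar
    with zero contigs gets mean 0 and an ``empty`` flag.
    """
    need = {"cultivar", "n_contigs", "total_bp"}
    if not need.issubset(table.columns):
        raise ValueError(f"summary table needs columns {sorted(need)}")
    out = table.copy()
    out["mean_bp"] = [
        mean_rounded(t, n) for t, n in zip(out["total_bp"], out["n_contigs"])
    ]
    out["empty"] = out["n_contigs"] == 0
    return out


def summarize_nonref_contigs(
    contigs_by_cultivar: dict[str, list], include_total: bool = True
) -> pd.DataFrame:
    """Per-cultivar non-reference contig counts, total bp and mean length.

    ``contigs_by_cultivar`` maps cultivar id to its (already QC-filtered)
    contig sequences. With ``include_total`` a pooled ``Total`` row over all
    cultivars' raw contigs is appended; note a published total may instead
    reflect a de-duplicated pool, which requires an explicit dedup map and
    is not guessed here.
    """
    from .qc import _seq_len

    rows = []
    for cultivar, contigs in contigs_by_cultivar.items():
        lengths = [_seq_len(c) for c in contigs]
        rows.append((cultivar, len(lengths), int(sum(lengths))))
    if include_total:
        rows.append(
            ("Total", sum(r[1] for r in rows), sum(r[2] for r in rows))
        )
    table = pd.DataFrame(rows, columns=["cultivar", "n_contigs", "total_bp"])
    return contig_summary_from_totals(table)
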