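"""Fixed-difference divergence scan between soft- and hard-seeded subpopulations.

A locus is *differentiated* when one subpopulation is fixed for the
reference allele and the other for the alternate allele, each side allowed
at most one heterozygous cultivar and no cultivar homozygous for the
opposite allele. Selected loci are merged into regions when consecutive
loci on a chromosome lie within ``merge_gap`` of each other; each region is
annotated with its nearest gene and, when it holds two or more loci, the
minimum pairwise r² among its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CultivarPanel,
    GeneModel,
    GenotypeMatrix,
    Region,
)
from .popgen import pairwise_r2

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    max_het_per_subpop: int = 1
    missing_policy: str = "exclude_locus"  # or "ignore_missing"
    min_called_fraction: float = 0.8  # used with ignore_missing
    merge_gap: int = 150_000  # bp
    region_r2_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.max_het_per_subpop < 0:
            raise ValueError("max_het_per_subpop must be >= 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.missing_policy not in ("exclude_locus", "ignore_missing"):
            raise ValueError(f"unknown missing policy {self.missing_policy!r}")


def _side_counts(calls: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int((calls == HOM_REF).sum()),
        int((calls == HET).sum()),
        int((calls == HOM_ALT).sum()),
        int((calls == MISSING).sum()),
    )


def locus_is_differentiated(
    calls: np.ndarray, panel: CultivarPanel, cfg: ScanConfig = ScanConfig()
) -> tuple[bool, str | None]:
    """Apply the fixed-difference rule to one locus.

    Returns (selected, orientation) with orientation one of
    ``ref_fixed_in_soft`` / ``ref_fixed_in_hard`` (which subpopulation
    carries the reference allele) or None when not selected.
    """
    panel.require_scan_ready()
    calls = np.asarray(calls)
    soft = calls[panel.indices("soft")]
    hard = calls[panel.indices("hard")]

    for side in (soft, hard):
        n_miss = int((side == MISSING).sum())
        if n_miss == side.size:
            return False, None  # nothing called on one side: ineligible
        if cfg.missing_policy == "exclude_locus":
            if n_miss > 0:
                return False, None
        else:
            if (side.size - n_miss) / side.size < cfg.min_called_fraction:
                return False, None

    s_ref, s_het, s_alt, _ = _side_counts(soft)
    h_ref, h_het, h_alt, _ = _side_counts(hard)
    max_het = cfg.max_het_per_subpop

    ref_in_soft = (
        s_alt == 0 and s_het <= max_het and s_ref > 0
        and h_ref == 0 and h_het <= max_het and h_alt > 0
    )
    ref_in_hard = (
        h_alt == 0 and h_het <= max_het and h_ref > 0
        and s_ref == 0 and s_het <= max_het and s_alt > 0
    )
    if ref_in_soft:
        return True, "ref_fixed_in_soft"
    if ref_in_hard:
        return True, "ref_fixed_in_hard"
    return False, None


def scan_genome(
    gm: GenotypeMatrix, panel: CultivarPanel, cfg: ScanConfig = ScanConfig()
) -> pd.DataFrame:
    """Evaluate every locus independently; return the selected ones.

    Output columns: chrom, pos, locus_index, orientation, sorted by
    (chrom, pos).
    """
    panel.require_scan_ready()
    if tuple(gm.cultivar_ids) != tuple(panel.cultivar_ids):
        raise ValueError("genotype matrix cultivars do not match panel")
    rows = []
    for i in range(gm.n_loci):
        ok, orientation = locus_is_differentiated(gm.calls[i], panel, cfg)
        if ok:
            rows.append(
                (
                    gm.loci["chrom"].iat[i],
                    int(gm.loci["pos"].iat[i]),
                    i,
                    orientation,
                )
            )
    out = pd.DataFrame(rows, columns=["chrom", "pos", "locus_index", "orientation"])
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    logger.info("scan selected %d of %d loci", len(out), gm.n_loci)
    return out


def merge_regions(selected: pd.DataFrame, merge_gap: int = 150_000) -> list[Region]:
    """Join consecutive selected loci within ``merge_gap`` on a chromosome.

    Single selected loci become single-position regions (start == end).
    Merging is idempotent and independent of input row order.
    """
    regions: list[Region] = []
    if selected.empty:
        return regions
    srt = selected.sort_values(["chrom", "pos"], kind="stable")
    for chrom, grp in srt.groupby("chrom", sort=True):
        positions = grp["pos"].to_list()
        orients = grp["orientation"].to_list()
        run = [positions[0]]
        run_orients = {orients[0]}
        for pos, ori in zip(positions[1:], orients[1:]):
            if pos - run[-1] <= merge_gap:
                run.append(pos)
                run_orients.add(ori)
            else:
                regions.append(_close_run(chrom, run, run_orients))
                run = [pos]
                run_orients = {ori}
        regions.append(_close_run(chrom, run, run_orients))
    return regions


def _close_run(chrom: str, run: list[int], orients: set) -> Region:
    orientation = orients.pop() if len(orients) == 1 else "mixed"
    return Region(
        chromosome=chrom,
        start=run[0],
        end=run[-1],
        members=list(run),
        orientation=orientation,
    )


def nearest_gene(
    region: Region, genes: list[GeneModel]
) -> tuple[str | None, int | None]:
    """The closest gene to a region on its chromosome.

    Distance is 0 when the region overlaps the gene interval, otherwise the
    gap between the nearest interval ends. Ties go to the gene with the
    smaller start. Returns (None, None) when the chromosome has no genes.
    """
    candidates = [g for g in genes if g.chromosome == region.chromosome]
    if not candidates:
        return None, None
    best: tuple[int, int, str] | None = None
    for g in candidates:
        if g.start <= region.end and region.start <= g.end:
            dist = 0
        elif g.start > region.end:
            dist = g.start - region.end
        else:
            dist = region.start - g.end
        key = (dist, g.start, g.gene_id)
        if best is None or key < best:
            best = key
    return best[2], best[0]


def region_r2_check(
    region: Region, gm: GenotypeMatrix, threshold: float = 0.95
) -> tuple[float | None, bool | None]:
    """Minimum pairwise r² among a region's member loci.

    Pass iff the minimum exceeds ``threshold`` (strict). Regions with fewer
    than two members are not applicable: returns (None, None).
    """
    if region.n_loci < 2:
        return None, None
    member_idx = np.flatnonzero(
        (gm.loci["chrom"] == region.chromosome).to_numpy()
        & gm.loci["pos"].isin(region.members).to_numpy()
    ).tolist()
    dosage = gm.dosage()
    r2s = []
    for ai in range(len(member_idx)):
        for bi in range(ai + 1, len(member_idx)):
            r2 = pairwise_r2(dosage[member_idx[ai]], dosage[member_idx[bi]])
            if not np.isnan(r2):
                r2s.append(r2)
    if not r2s:
        return None, None
    min_r2 = float(min(r2s))
    return min_r2, min_r2 > threshold


def annotate_regions(
    regions: list[Region],
    genes: list[GeneModel],
    gm: GenotypeMatrix | None = None,
    cfg: ScanConfig = ScanConfig(),
) -> list[Region]:
    """Attach nearest gene (and min r² when genotypes given) to each region."""
    for region in regions:
        region.nearest_gene_id, region.nearest_gene_distance = nearest_gene(
            region, genes
        )
        if gm is not None and region.n_loci >= 2:
            region.min_r2, _ = region_r2_check(region, gm, cfg.region_r2_threshold)
    return regions


def regions_table(regions: list[Region], genes: list[GeneModel]) -> pd.DataFrame:
    """Tabular report mirroring the usual region/nearest-gene layout."""
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for r in regions:
        position = (
            f"{r.start:,}" if r.start == r.end else f"{r.start:,} to {r.end:,}"
        )
        gene = by_id.get(r.nearest_gene_id) if r.nearest_gene_id else None
        rows.append(
            {
                "chrom": r.chromosome,
                "position": position,
                "n_loci": r.n_loci,
                "orientation": r.orientation,
                "gene": r.nearest_gene_id,
                "gene_start": gene.start if gene else None,
                "gene_end": gene.end if gene else None,
                "annotation": gene.annotation if gene else None,
                "gene_distance": r.nearest_gene_distance,
                "min_r2": r.min_r2,
            }
        )
    return pd.DataFrame(rows)
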