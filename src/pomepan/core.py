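"""Core containers shared across the pipeline.

Genotypes are stored as small integer codes in a loci x cultivars array:

====  ==========
code  meaning
====  ==========
0     homozygous reference
1     heterozygous
2     homozygous alternate
-1    missing / uncalled
====  ==========

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

SUBPOPULATIONS = ("soft", "hard", "unassigned")


@dataclass(frozen=True)
class CultivarPanel:
    """Cultivar identifiers with their seed-phenotype subpopulation labels."""

    cultivar_ids: tuple[str, ...]
    subpopulations: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.cultivar_ids) != len(self.subpopulations):
            raise ValueError("cultivar_ids and subpopulations differ in length")
        if len(set(self.cultivar_ids)) != len(self.cultivar_ids):
            raise ValueError("duplicate cultivar ids in panel")
        bad = set(self.subpopulations) - set(SUBPOPULATIONS)
        if bad:
            raise ValueError(f"unknown subpopulation labels: {sorted(bad)}")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "CultivarPanel":
        return cls(tuple(mapping), tuple(mapping.values()))

    def members(self, subpopulation: str) -> list[str]:
        return [
            c
            for c, s in zip(self.cultivar_ids, self.subpopulations)
            if s == subpopulation
        ]

    def indices(self, subpopulation: str) -> np.ndarray:
        return np.array(
            [
                i
                for i, s in enumerate(self.subpopulations)
                if s == subpopulation
            ],
            dtype=int,
        )

    def require_scan_ready(self) -> None:
        """A divergence scan needs at least one cultivar on each side."""
        if not self.members("soft") or not self.members("hard"):
            raise ValueError(
                "divergence scan requires both soft and hard subpopulations"
            )


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP calls for loci x cultivars.

    ``loci`` holds columns chrom, pos, ref, alt; positions are strictly
    increasing within each chromosome. ``calls`` is an int8 array using the
    module-level genotype codes.
    """

    loci: pd.DataFrame
    calls: np.ndarray
    cultivar_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.cultivar_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.cultivar_ids)} cultivars"
            )
        expected = {"chrom", "pos", "ref", "alt"}
        if not expected.issubset(self.loci.columns):
            raise ValueError(f"loci frame must have columns {sorted(expected)}")
        for chrom, grp in self.loci.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on {chrom}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivar_ids)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0, 1, 2) with missing as NaN, float array."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def column(self, cultivar_id: str) -> np.ndarray:
        return self.calls[:, self.cultivar_ids.index(cultivar_id)]


@dataclass(frozen=True)
class GeneModel:
    """One gene feature: 1-based inclusive coordinates plus free-text annotation."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with PHRED qualities and its library class."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    library_class: str = "paired_end"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )
        if self.library_class not in ("paired_end", "mate_pair"):
            raise ValueError(f"unknown library class {self.library_class!r}")


@dataclass(frozen=True)
class ContigHitSet:
    """A contig's length and its alignment hits against screening databases.

    Hits are (start, end, identity_pct, evalue) with 1-based inclusive
    coordinates on the contig.
    """

    contig_id: str
    contig_len: int
    hits: tuple[tuple[int, int, float, float], ...] = ()

    def __post_init__(self) -> None:
        for start, end, _ident, _ev in self.hits:
            if not (1 <= start <= end <= self.contig_len):
                raise ValueError(
                    f"contig {self.contig_id}: hit {start}-{end} outside "
                    f"1..{self.contig_len}"
                )


@dataclass
class Region:
    """A merged run of differentiated loci with its nearest-gene assignment."""

    chromosome: str
    start: int
    end: int
    members: list[int] = field(default_factory=list)  # positions, sorted
    orientation: str | None = None
    nearest_gene_id: str | None = None
    nearest_gene_distance: int | None = None
    min_r2: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        self.members = sorted(self.members)

    @property
    def n_loci(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class PAVMatrix:
    """Binary gene presence/absence: genes x cultivars."""

    gene_ids: tuple[str, ...]
    cultivar_ids: tuple[str, ...]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.gene_ids), len(self.cultivar_ids)):
            raise ValueError("presence shape does not match ids")
        if len(set(self.cultivar_ids)) != len(self.cultivar_ids):
            raise ValueError("duplicate cultivar ids")
        if self.presence.size and not self.presence.any(axis=1).all():
            bad = [
                g
                for g, row in zip(self.gene_ids, self.presence)
                if not row.any()
            ]
            raise ValueError(
                f"{len(bad)} gene(s) absent from every cultivar "
                f"(first: {bad[0]}); a pan-gene must be present somewhere"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivar_ids)

    def n_present(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.astype(int),
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.cultivar_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PAVMatrix":
        return cls(
            tuple(frame.index.astype(str)),
            tuple(frame.columns.astype(str)),
            frame.to_numpy(dtype=bool),
        )
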