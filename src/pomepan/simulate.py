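"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover the pipeline end to end with no external data:

* :func:`simulate_pav` — an 11-cultivar-style gene presence/absence matrix
  with exact (quota-sampled) category composition, in which two "donor"
  cultivars carry almost all non-shared genes;
* :func:`simulate_genotypes` — a diploid SNP panel split into soft- and
  hard-seeded subpopulations with planted fixed-difference regions,
  subpopulation-specific heterozygosity and distance-dependent LD;
* :func:`simulate_reads_and_contigs` — FASTQ reads and FASTA contigs with
  planted QC failures and contaminants plus a hit table.

Every generator is driven by a single integer seed and emits a truth table
sufficient to score the downstream stage; recovery tests never re-derive
truth from the simulated data itself. The same seed reproduces outputs
byte-identically.

LD is induced by a copying model: each cultivar carries a latent allelic
state chain along each chromosome that copies the previous locus' state
with probability exp(-d / ld_block_len) for inter-locus distance d, and
otherwise redraws from the locus allele frequency. Heterozygous calls are
then overlaid at the subpopulation's het rate, so per-individual
heterozygosity is directly the specified rate while homozygous dosages
carry the distance-dependent correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ContigHitSet,
    CultivarPanel,
    GenotypeMatrix,
    PAVMatrix,
    ReadRecord,
)
from .rounding import round_half_away

# The 11-cultivar pomegranate panel; Taishanhong and Tunisia are the two
# donor cultivars that carry nearly all non-shared gene content.
PAN_CULTIVARS = (
    "Achygdona",
    "AG2017",
    "Bhagawa",
    "Dabenzi",
    "Fatima",
    "Gizili",
    "Goynar",
    "Purpursid",
    "Taishanhong",
    "Tunisia",
    "Valas",
)
DONOR_CULTIVARS = ("Taishanhong", "Tunisia")


@dataclass(frozen=True)
class PavSimSpec:
    """Composition targets for a simulated PAV matrix.

    Fractions follow the pomegranate pan-genome composition: 81.3% of genes
    in all cultivars, 1.8% missing from exactly one, 4.3% dispensable and
    12.6% cultivar-specific, with 97.2% of specific genes carried by the
    two donor cultivars.
    """

    n_genes: int = 31_016
    cultivars: tuple[str, ...] = PAN_CULTIVARS
    fraction_core_all: float = 0.813
    fraction_missing_one: float = 0.018
    fraction_dispensable: float = 0.043
    fraction_specific: float = 0.126
    donor_cultivars: tuple[str, ...] = DONOR_CULTIVARS
    donor_bias: float = 0.972
    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.fraction_core_all
            + self.fraction_missing_one
            + self.fraction_dispensable
            + self.fraction_specific
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {total}, not 1")
        if not 0 <= self.donor_bias <= 1:
            raise ValueError("donor_bias must be in [0, 1]")
        unknown = set(self.donor_cultivars) - set(self.cultivars)
        if unknown:
            raise ValueError(f"donor cultivar(s) not in panel: {sorted(unknown)}")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "present_in_all": self.fraction_core_all,
            "missing_from_one": self.fraction_missing_one,
            "dispensable": self.fraction_dispensable,
            "specific": self.fraction_specific,
        }


def category_quotas(spec: PavSimSpec) -> dict[str, int]:
    """Exact per-category gene counts: rounded targets, residual to the
    largest category so quotas always sum to n_genes."""
    quotas = {
        cat: int(round_half_away(frac * spec.n_genes))
        for cat, frac in spec.fractions.items()
    }
    largest = max(quotas, key=lambda c: quotas[c])
    quotas[largest] += spec.n_genes - sum(quotas.values())
    if any(v < 0 for v in quotas.values()):
        raise ValueError("quota rounding produced a negative count")
    return quotas


def simulate_pav(spec: PavSimSpec) -> tuple[PAVMatrix, pd.DataFrame]:
    """Quota-sampled PAV matrix plus a per-gene truth table.

    Realized category counts equal the rounded targets exactly. With
    probability ``donor_bias`` a specific/dispensable gene's carriers are
    drawn from the donor cultivars (filled from the rest when the carrier
    set is larger than the donor set); otherwise carriers come from the
    non-donor cultivars.
    """
    n_nonzero = sum(1 for f in spec.fractions.values() if f > 0)
    if spec.n_genes < n_nonzero:
        raise ValueError(
            f"n_genes={spec.n_genes} below the {n_nonzero} categories requested"
        )
    rng = np.random.default_rng(spec.seed)
    n_cult = len(spec.cultivars)
    donors = [spec.cultivars.index(d) for d in spec.donor_cultivars]
    non_donors = [i for i in range(n_cult) if i not in donors]
    quotas = category_quotas(spec)

    presence = np.zeros((spec.n_genes, n_cult), dtype=bool)
    categories: list[str] = []
    gene = 0
    for cat, quota in quotas.items():
        for _ in range(quota):
            row = presence[gene]
            if cat == "present_in_all":
                row[:] = True
            elif cat == "missing_from_one":
                row[:] = True
                row[rng.integers(n_cult)] = False
            elif cat == "specific":
                pool = donors if rng.random() < spec.donor_bias else non_donors
                row[pool[rng.integers(len(pool))]] = True
            else:  # dispensable: 2 .. n_cult - 2 carriers
                k = int(rng.integers(2, n_cult - 1))
                if rng.random() < spec.donor_bias:
                    chosen = list(rng.permutation(donors)[: min(k, len(donors))])
                    if k > len(chosen):
                        chosen += list(
                            rng.choice(non_donors, size=k - len(chosen), replace=False)
                        )
                else:
                    chosen = list(rng.choice(non_donors, size=min(k, len(non_donors)), replace=False))
                row[chosen] = True
            categories.append(cat)
            gene += 1

    gene_ids = tuple(f"gene{str(i + 1).zfill(6)}" for i in range(spec.n_genes))
    pav = PAVMatrix(gene_ids, spec.cultivars, presence)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": categories,
            "n_present": presence.sum(axis=1),
            "carriers": [
                ",".join(c for c, p in zip(spec.cultivars, row) if p)
                for row in presence
            ],
        }
    )
    return pav, truth


def pomegranate_pan_composition() -> PAVMatrix:
    """Deterministic PAV matrix realizing the pomegranate pan-genome
    composition exactly.

    31,016 genes over the 11-cultivar panel: 25,210 in all cultivars, 552
    missing from exactly one (324 of them missing from a donor), 1,338
    dispensable and 3,916 cultivar-specific (3,805 carried by the donors
    Taishanhong/Tunisia). The donor pair covers 30,667 genes, Purpursid
    adds 198 more and the remaining eight cultivars the last 151.
    """
    cultivars = PAN_CULTIVARS
    n_cult = len(cultivars)
    tai = cultivars.index("Taishanhong")
    tun = cultivars.index("Tunisia")
    pur = cultivars.index("Purpursid")
    others = [i for i in range(n_cult) if i not in (tai, tun)]
    others_no_pur = [i for i in others if i != pur]

    rows: list[np.ndarray] = []

    def blank() -> np.ndarray:
        return np.zeros(n_cult, dtype=bool)

    # 25,210 genes present in every cultivar
    for _ in range(25_210):
        rows.append(np.ones(n_cult, dtype=bool))
    # 552 missing from exactly one: 324 missing from a donor, 228 from others
    for i in range(324):
        row = np.ones(n_cult, dtype=bool)
        row[tai if i % 2 == 0 else tun] = False
        rows.append(row)
    for i in range(228):
        row = np.ones(n_cult, dtype=bool)
        row[others[i % len(others)]] = False
        rows.append(row)
    # 1,338 dispensable (2..9 carriers): 1,100 include a donor, 238 do not
    for i in range(1_100):
        row = blank()
        row[tai if i % 2 == 0 else tun] = True
        k = 2 + i % 8  # carriers 2..9
        for j in range(k - 1):
            row[others[(i + j) % len(others)]] = True
        rows.append(row)
    for i in range(148):  # no donor, include Purpursid
        row = blank()
        row[pur] = True
        k = 2 + i % 8
        for j in range(k - 1):
            row[others_no_pur[(i + j) % len(others_no_pur)]] = True
        rows.append(row)
    for i in range(90):  # no donor, no Purpursid
        row = blank()
        k = 2 + i % 7  # carriers 2..8 from the remaining eight cultivars
        for j in range(k):
            row[others_no_pur[(i + j) % len(others_no_pur)]] = True
        rows.append(row)
    # 3,916 cultivar-specific: 3,805 on a donor, 50 on Purpursid, 61 elsewhere
    for i in range(3_805):
        row = blank()
        row[tai if i % 2 == 0 else tun] = True
        rows.append(row)
    for _ in range(50):
        row = blank()
        row[pur] = True
        rows.append(row)
    for i in range(61):
        row = blank()
        row[others_no_pur[i % len(others_no_pur)]] = True
        rows.append(row)

    presence = np.vstack(rows)
    gene_ids = tuple(f"pan{str(i + 1).zfill(6)}" for i in range(len(rows)))
    return PAVMatrix(gene_ids, cultivars, presence)


# ------------------------------------------------------------ genotype panel


def default_scan_panel(n_soft: int = 20, n_hard: int = 19) -> CultivarPanel:
    """A labelled two-subpopulation panel (soft01.., hard01..)."""
    ids = [f"soft{i + 1:02d}" for i in range(n_soft)] + [
        f"hard{i + 1:02d}" for i in range(n_hard)
    ]
    subpops = ["soft"] * n_soft + ["hard"] * n_hard
    return CultivarPanel(tuple(ids), tuple(subpops))


#: planted fixed-difference layout mimicking the observed divergence map:
#: one ~135 kb four-locus cluster plus eight isolated loci over two chromosomes
DEFAULT_PLANTED_REGIONS = (
    ("chr1", 11_360_000, 11_500_000, 4),
    ("chr1", 5_170_000, 5_180_000, 1),
    ("chr1", 16_540_000, 16_550_000, 1),
    ("chr1", 23_430_000, 23_440_000, 1),
    ("chr1", 34_330_000, 34_340_000, 1),
    ("chr2", 7_220_000, 7_230_000, 1),
    ("chr2", 11_260_000, 11_270_000, 1),
    ("chr2", 20_380_000, 20_390_000, 1),
    ("chr2", 20_930_000, 20_940_000, 1),
)


@dataclass(frozen=True)
class GenoSimSpec:
    """Structure of a simulated two-subpopulation diploid SNP panel."""

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 40_000_000),
        ("chr2", 25_000_000),
    )
    n_loci_per_chromosome: int = 2_500
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    het_rate_soft: float = 0.12
    het_rate_hard: float = 0.30
    missing_rate: float = 0.02
    planted_regions: tuple[tuple[str, int, int, int], ...] = DEFAULT_PLANTED_REGIONS
    ld_block_len: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, start, end, n_fixed in self.planted_regions:
            if chrom not in lengths:
                raise ValueError(f"planted region on unknown chromosome {chrom}")
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(
                    f"planted region {chrom}:{start}-{end} outside chromosome"
                )
            if n_fixed > end - start + 1:
                raise ValueError(
                    f"region {chrom}:{start}-{end} cannot hold {n_fixed} loci"
                )
        for rate in (
            self.het_rate_soft,
            self.het_rate_hard,
            self.missing_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.ld_block_len < 0:
            raise ValueError("ld_block_len must be >= 0")


_BASES = np.array(list("ACGT"))


def simulate_genotypes(
    spec: GenoSimSpec, panel: CultivarPanel
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the diploid panel; returns (genotypes, planted-locus truth).

    Planted loci are homozygous reference in the soft subpopulation and
    homozygous alternate in the hard one before missing-data masking;
    background loci share per-locus allele frequencies across
    subpopulations, carry the subpopulation's het rate, and are correlated
    along the chromosome by the copying model (see module docstring).
    """
    rng = np.random.default_rng(spec.seed)
    n_cult = len(panel.cultivar_ids)
    het_rate = np.array(
        [
            spec.het_rate_soft
            if s == "soft"
            else spec.het_rate_hard
            if s == "hard"
            else (spec.het_rate_soft + spec.het_rate_hard) / 2
            for s in panel.subpopulations
        ]
    )
    soft_idx = panel.indices("soft")
    hard_idx = panel.indices("hard")

    loci_frames = []
    call_blocks = []
    truth_rows = []
    for chrom, length in spec.chromosomes:
        planted_here = [r for r in spec.planted_regions if r[0] == chrom]
        planted_pos: list[int] = []
        for _chrom, start, end, n_fixed in planted_here:
            width = end - start + 1
            if n_fixed >= width:
                pos = np.arange(start, start + n_fixed)
            else:
                pos = start + np.sort(
                    rng.choice(width, size=n_fixed, replace=False)
                )
            planted_pos.extend(int(p) for p in pos)

        n_bg = spec.n_loci_per_chromosome
        taken = set(planted_pos)
        bg_pos: list[int] = []
        while len(bg_pos) < n_bg:
            draw = rng.integers(1, length + 1, size=2 * (n_bg - len(bg_pos)))
            for p in draw:
                p = int(p)
                if p not in taken:
                    taken.add(p)
                    bg_pos.append(p)
                    if len(bg_pos) == n_bg:
                        break
        positions = np.array(sorted(set(planted_pos) | set(bg_pos)))
        planted_mask = np.isin(positions, np.array(planted_pos, dtype=positions.dtype))
        n_loci = positions.size

        freqs = rng.uniform(*spec.allele_freq_range, size=n_loci)
        # latent allelic state chain per cultivar (copying model)
        z = np.empty((n_loci, n_cult), dtype=np.int8)
        z[0] = rng.random(n_cult) < freqs[0]
        dists = np.diff(positions)
        if spec.ld_block_len > 0:
            copy_p = np.exp(-dists / spec.ld_block_len)
        else:
            copy_p = np.zeros_like(dists, dtype=float)
        for j in range(1, n_loci):
            copy = rng.random(n_cult) < copy_p[j - 1]
            fresh = (rng.random(n_cult) < freqs[j]).astype(np.int8)
            z[j] = np.where(copy, z[j - 1], fresh)

        calls = (2 * z).astype(np.int8)  # HOM_REF / HOM_ALT from latent state
        het_mask = rng.random((n_loci, n_cult)) < het_rate[None, :]
        calls[het_mask] = HET

        # plant fixed differences (overrides background and het overlay)
        calls[np.ix_(planted_mask, soft_idx)] = HOM_REF
        calls[np.ix_(planted_mask, hard_idx)] = HOM_ALT

        if spec.missing_rate > 0:
            miss = rng.random((n_loci, n_cult)) < spec.missing_rate
            calls[miss] = MISSING

        ref_idx = rng.integers(0, 4, size=n_loci)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
        loci_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": positions,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                }
            )
        )
        call_blocks.append(calls)
        for p in sorted(planted_pos):
            truth_rows.append((chrom, p))

    gm = GenotypeMatrix(
        pd.concat(loci_frames, ignore_index=True),
        np.vstack(call_blocks),
        tuple(panel.cultivar_ids),
    )
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos"])
    return gm, truth


# -------------------------------------------------------- reads and contigs


@dataclass(frozen=True)
class ReadContigSimSpec:
    """Counts of clean and planted-failure records to generate."""

    n_clean_reads: int = 50
    n_consecutive_n: int = 3
    n_low_quality: int = 3
    n_short: int = 3
    read_len: int = 100
    n_clean_contigs: int = 5
    n_contaminants: int = 3
    n_short_contigs: int = 2
    seed: int = 0


def simulate_reads_and_contigs(
    spec: ReadContigSimSpec = ReadContigSimSpec(),
) -> tuple[list[ReadRecord], list[tuple[str, str]], list[ContigHitSet], pd.DataFrame]:
    """Reads, contigs and hit tables with planted QC failures.

    Each planted read failure violates exactly one read-filter rule
    (a run of four Ns; four bases at Q20; a 40 bp read) and each planted
    contaminant contig exceeds the 25%-of-length aggregate hit threshold
    at over 70% identity. Returns (reads, contigs, hitsets, truth) where
    truth has columns record_type, record_id, label.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[ReadRecord] = []
    truth_rows: list[tuple[str, str, str]] = []

    def random_seq(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    def good_quals(n: int) -> tuple[int, ...]:
        return tuple(int(q) for q in rng.integers(28, 41, size=n))

    for i in range(spec.n_clean_reads):
        rid = f"read_clean_{i + 1:03d}"
        reads.append(
            ReadRecord(rid, random_seq(spec.read_len), good_quals(spec.read_len))
        )
        truth_rows.append(("read", rid, "pass"))
    for i in range(spec.n_consecutive_n):
        rid = f"read_nrun_{i + 1:03d}"
        seq = list(random_seq(spec.read_len))
        at = int(rng.integers(0, spec.read_len - 4))
        seq[at : at + 4] = "NNNN"
        reads.append(ReadRecord(rid, "".join(seq), good_quals(spec.read_len)))
        truth_rows.append(("read", rid, "consecutive_n"))
    for i in range(spec.n_low_quality):
        rid = f"read_lowq_{i + 1:03d}"
        quals = list(good_quals(spec.read_len))
        for at in rng.choice(spec.read_len, size=4, replace=False):
            quals[int(at)] = 20
        reads.append(ReadRecord(rid, random_seq(spec.read_len), tuple(quals)))
        truth_rows.append(("read", rid, "low_quality_bases"))
    for i in range(spec.n_short):
        rid = f"read_short_{i + 1:03d}"
        reads.append(ReadRecord(rid, random_seq(40), good_quals(40)))
        truth_rows.append(("read", rid, "length"))

    contigs: list[tuple[str, str]] = []
    hitsets: list[ContigHitSet] = []
    for i in range(spec.n_clean_contigs):
        cid = f"contig_clean_{i + 1:03d}"
        n = int(rng.integers(1_500, 3_001))
        contigs.append((cid, random_seq(n)))
        # one modest passing hit (~10% of length) and one identity-gated hit
        hits = (
            (1, max(101, n // 10), 85.0, 1e-20),
            (n // 2, n // 2 + 200, 60.0, 1e-30),
        )
        hitsets.append(ContigHitSet(cid, n, hits))
        truth_rows.append(("contig", cid, "clean"))
    for i in range(spec.n_contaminants):
        cid = f"contig_contam_{i + 1:03d}"
        n = int(rng.integers(1_200, 2_501))
        contigs.append((cid, random_seq(n)))
        span = int(0.4 * n)  # two overlapping hits whose union covers 40%
        hits = (
            (1, span // 2 + 60, 88.0, 1e-25),
            (span // 2 - 60, span, 91.0, 1e-25),
        )
        hitsets.append(ContigHitSet(cid, n, hits))
        truth_rows.append(("contig", cid, "contaminant"))
    for i in range(spec.n_short_contigs):
        cid = f"contig_short_{i + 1:03d}"
        n = int(rng.integers(200, 1_001))
        contigs.append((cid, random_seq(n)))
        hitsets.append(ContigHitSet(cid, n, ()))
        truth_rows.append(("contig", cid, "short"))

    truth = pd.DataFrame(truth_rows, columns=["record_type", "record_id", "label"])
    return reads, contigs, hitsets, truth
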