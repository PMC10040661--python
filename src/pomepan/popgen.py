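"""Heterozygosity and linkage-disequilibrium decay statistics.

Heterozygosity is per individual: the fraction of its called genotypes that
are heterozygous. Subpopulation values are unweighted means over members.

LD is measured as the squared Pearson correlation of alt-allele dosages
(0/1/2) between two loci over the cultivars called at both — the composite
(genotype-level) r² customary for unphased SNP matrices. Decay curves fit a
locally weighted quadratic (degree-2 loess with tricube weights) of r²
against physical distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, CultivarPanel, GenotypeMatrix

logger = logging.getLogger(__name__)


def heterozygosity(
    gm: GenotypeMatrix, panel: CultivarPanel | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cultivar heterozygous fraction, plus per-subpopulation means.

    Missing calls are excluded from each cultivar's denominator; a cultivar
    with no called loci is flagged and left out of its subpopulation mean.
    """
    called = gm.calls != MISSING
    n_called = called.sum(axis=0)
    n_het = (gm.calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    per_cultivar = pd.DataFrame(
        {
            "cultivar": list(gm.cultivar_ids),
            "n_called": n_called,
            "n_het": n_het,
            "heterozygosity": het,
        }
    )
    if (n_called == 0).any():
        logger.warning(
            "%d cultivar(s) with zero called loci excluded from subpopulation means",
            int((n_called == 0).sum()),
        )
    by_subpop: dict[str, float] = {}
    if panel is not None:
        per_cultivar["subpopulation"] = [
            panel.subpopulations[panel.cultivar_ids.index(c)]
            for c in gm.cultivar_ids
        ]
        for sp in sorted(set(panel.subpopulations)):
            vals = per_cultivar.loc[
                (per_cultivar["subpopulation"] == sp)
                & per_cultivar["heterozygosity"].notna(),
                "heterozygosity",
            ]
            by_subpop[sp] = float(vals.mean()) if len(vals) else float("nan")
    return per_cultivar, by_subpop


def pairwise_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite r² between two loci from their dosage vectors.

    Missing calls are NaN; only cultivars called at both loci enter. Returns
    NaN when either locus is monomorphic in that shared set (r² undefined).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    r = float((a * b).sum() / denom)
    return min(r * r, 1.0)


def loess_quadratic(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.3,
) -> np.ndarray:
    """Degree-2 loess: local quadratic fits with tricube distance weights.

    At each grid point the nearest ``ceil(span * n)`` observations get
    tricube weights and a weighted quadratic is fitted and evaluated there.
    Windows too degenerate for a quadratic (under three distinct x) fall
    back to a weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = x.size
    q = max(int(np.ceil(span * n)), 3)
    q = min(q, n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dq = d[idx]
        dmax = dq.max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1 - np.minimum(dq / dmax, 1.0) ** 3) ** 3
        xi, yi = xs[idx], ys[idx]
        keep = w > 0
        if keep.sum() < 3 or np.unique(xi[keep]).size < 3:
            out[i] = float(np.average(yi, weights=np.maximum(w, 1e-12)))
            continue
        # weighted least squares on centered x for conditioning
        xc = xi - x0
        coeffs = np.polyfit(xc, yi, deg=2, w=np.sqrt(w))
        out[i] = float(np.polyval(coeffs, 0.0))
    return out


@dataclass
class LdDecayCurve:
    """Raw distance/r² pairs and the smoothed decay curve."""

    pairs: pd.DataFrame  # columns: chrom, distance_bp, r2
    smoothed: pd.DataFrame  # columns: distance_bp, r2_smooth (may be empty)
    span: float

    def r2_at(self, distance_bp: float) -> float:
        """Smoothed r² at a distance, by interpolation on the fitted grid."""
        if self.smoothed.empty:
            return float("nan")
        return float(
            np.interp(
                distance_bp,
                self.smoothed["distance_bp"],
                self.smoothed["r2_smooth"],
            )
        )


def ld_decay(
    gm: GenotypeMatrix,
    cultivars: list[str] | None = None,
    max_dist: int = 1_000_000,
    span: float = 0.3,
    grid_points: int = 100,
    max_pairs: int = 500_000,
    seed: int | None = None,
) -> LdDecayCurve:
    """LD decay curve over all same-chromosome locus pairs within max_dist.

    ``cultivars`` restricts the panel (e.g. to one subpopulation). Pairs with
    undefined r² (monomorphic locus in the shared called set) are dropped.
    When the number of eligible pairs exceeds ``max_pairs`` a seeded uniform
    subsample is used.
    """
    if cultivars is not None:
        idx = [gm.cultivar_ids.index(c) for c in cultivars]
        dosage = gm.dosage()[:, idx]
    else:
        dosage = gm.dosage()
    chroms = gm.loci["chrom"].to_numpy()
    pos = gm.loci["pos"].to_numpy()

    pair_idx: list[tuple[int, int]] = []
    for chrom in pd.unique(chroms):
        where = np.flatnonzero(chroms == chrom)
        p = pos[where]
        for a in range(len(where)):
            # positions are sorted within chromosome; stop once too far
            for b in range(a + 1, len(where)):
                if p[b] - p[a] > max_dist:
                    break
                pair_idx.append((where[a], where[b]))
    if not pair_idx:
        logger.warning("no eligible locus pairs within %d bp", max_dist)
        empty = pd.DataFrame(columns=["chrom", "distance_bp", "r2"])
        return LdDecayCurve(empty, pd.DataFrame(columns=["distance_bp", "r2_smooth"]), span)

    if len(pair_idx) > max_pairs:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(pair_idx), size=max_pairs, replace=False)
        pair_idx = [pair_idx[i] for i in np.sort(chosen)]

    rows = []
    for a, b in pair_idx:
        r2 = pairwise_r2(dosage[a], dosage[b])
        if np.isnan(r2):
            continue
        rows.append((chroms[a], int(pos[b] - pos[a]), r2))
    pairs = pd.DataFrame(rows, columns=["chrom", "distance_bp", "r2"])

    if len(pairs) < 3:
        logger.warning("only %d raw pair(s); smoothing skipped", len(pairs))
        smoothed = pd.DataFrame(columns=["distance_bp", "r2_smooth"])
        return LdDecayCurve(pairs, smoothed, span)

    grid = np.linspace(
        pairs["distance_bp"].min(), pairs["distance_bp"].max(), grid_points
    )
    fitted = loess_quadratic(
        pairs["distance_bp"].to_numpy(), pairs["r2"].to_numpy(), grid, span
    )
    smoothed = pd.DataFrame({"distance_bp": grid, "r2_smooth": fitted})
    return LdDecayCurve(pairs, smoothed, span)


def plot_ld_decay(curves: dict[str, LdDecayCurve], path: str) -> None:
    """Write a decay plot (smoothed curves per labelled panel) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        if curve.smoothed.empty:
            continue
        ax.plot(
            curve.smoothed["distance_bp"] / 1e3,
            curve.smoothed["r2_smooth"],
            label=label,
        )
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"$r^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
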