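"""Pairwise genotype-dependence statistic and the exhaustive SNP-pair scan.

For one SNP pair within one phenotype group, genotypes are encoded
w -> -1, h -> 0, v -> +1 and the dependence statistic is the closed form

    rho = (P_ww - P_wv - P_vw + P_vv)
          / sqrt( (P_{x=w} + P_{x=v}) * (P_{y=w} + P_{y=v}) )

over the 3x3 joint genotype probability table of the group — equivalently
E[xy] / sqrt(E[x^2] E[y^2]) on the encoded values.  Heterozygotes encode to
zero, so only homozygote cells enter; rho is undefined when a SNP has no
homozygotes in the group (zero marginal factor).  No mean-centering is
applied: the closed form above is the statistic, which coincides with the
Pearson correlation only when the encoded means vanish.

The disease signal for a pair is the case/control contrast
``rho_diff = |rho_control - rho_case|``; linkage disequilibrium and other
disease-unrelated dependence affects both groups alike and cancels.

The full scan visits all N(N-1)/2 unordered pairs.  It accumulates exact
int64 counts (joint homozygote tallies, homozygote marginals, pairwise
complete-case sizes), so emitted scores are bit-identical for every chunk
size and worker count.  Missing genotypes are dropped pair-by-pair within
each group (pairwise complete-case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from joblib import Parallel, delayed

from .genotype_io import MISSING, GenotypeMatrix, PhenotypeLabels

__all__ = [
    "EncodedGenotypes",
    "JointGenotypeTable",
    "PairScore",
    "encode_genotypes",
    "build_joint_table",
    "rho",
    "score_pair",
    "all_pairs_scan",
    "scan_to_records",
    "pair_count",
    "PAIR_DTYPE",
]


@dataclass
class EncodedGenotypes:
    """Per-individual encoded genotype values with an observed-data mask."""

    values: np.ndarray  # int8 in {-1, 0, +1}; arbitrary where mask is False
    mask: np.ndarray  # bool, True = observed


def encode_genotypes(codes: np.ndarray) -> EncodedGenotypes:
    """Map genotype codes {0,1,2} to {-1,0,+1}; missing (-9) masked out."""
    codes = np.asarray(codes)
    mask = codes != MISSING
    values = np.where(mask, codes - 1, 0).astype(np.int8)
    return EncodedGenotypes(values=values, mask=mask)


@dataclass
class JointGenotypeTable:
    """3x3 joint genotype probability table for one SNP pair in one group.

    ``p[a, b]`` is the fraction of the group's pairwise-complete individuals
    with genotype a at SNP x and b at SNP y, indices ordered (w, h, v).
    """

    p: np.ndarray  # float64 (3, 3)
    n_used: int

    @property
    def empty(self) -> bool:
        return self.n_used == 0


def build_joint_table(gx: np.ndarray, gy: np.ndarray, group_mask: np.ndarray) -> JointGenotypeTable:
    """Tally the 3x3 joint genotype table over one group.

    Individuals with a missing genotype at either SNP are excluded
    (pairwise complete-case); probabilities are counts / n_used.
    """
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    group_mask = np.asarray(group_mask, dtype=bool)
    if not (gx.shape == gy.shape == group_mask.shape):
        raise ValueError("gx, gy and group_mask must have identical length")
    use = group_mask & (gx != MISSING) & (gy != MISSING)
    n_used = int(use.sum())
    if n_used == 0:
        return JointGenotypeTable(p=np.zeros((3, 3)), n_used=0)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (gx[use], gy[use]), 1)
    return JointGenotypeTable(p=counts / n_used, n_used=n_used)


def rho(t: JointGenotypeTable) -> float:
    """Genotype-dependence statistic from a joint table; NaN when undefined.

    Undefined when the table is empty or either SNP has no homozygotes in
    the group (a zero marginal factor (P_w + P_v)).
    """
    if t.empty:
        return math.nan
    p = t.p
    mx = p[0, :].sum() + p[2, :].sum()  # P(x=w) + P(x=v)
    my = p[:, 0].sum() + p[:, 2].sum()
    if mx == 0.0 or my == 0.0:
        return math.nan
    num = p[0, 0] - p[0, 2] - p[2, 0] + p[2, 2]
    return num / math.sqrt(mx * my)


@dataclass
class PairScore:
    """One SNP pair's per-group statistics and their contrast."""

    i: int
    j: int
    rho_case: float
    rho_control: float
    rho_diff: float
    n_case_used: int
    n_ctrl_used: int
    valid: bool

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


def score_pair(
    gx: np.ndarray,
    gy: np.ndarray,
    case_mask: np.ndarray,
    control_mask: np.ndarray,
    i: int = 0,
    j: int = 1,
) -> PairScore:
    """Score one SNP pair: rho per group and rho_diff = |rho_ctrl - rho_case|.

    The pair is invalid (scores NaN) if rho is undefined in either group.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    if (case_mask & control_mask).any():
        raise ValueError("case and control masks overlap")
    if not case_mask.any() or not control_mask.any():
        raise ValueError("each group must be nonempty")
    t_case = build_joint_table(gx, gy, case_mask)
    t_ctrl = build_joint_table(gx, gy, control_mask)
    r_case = rho(t_case)
    r_ctrl = rho(t_ctrl)
    valid = not (math.isnan(r_case) or math.isnan(r_ctrl))
    return PairScore(
        i=i,
        j=j,
        rho_case=r_case,
        rho_control=r_ctrl,
        rho_diff=abs(r_ctrl - r_case) if valid else math.nan,
        n_case_used=t_case.n_used,
        n_ctrl_used=t_ctrl.n_used,
        valid=valid,
    )


def pair_count(n_snps: int) -> int:
    """Number of unordered SNP pairs, N(N-1)/2."""
    if n_snps < 2:
        raise ValueError("need at least two SNPs")
    return n_snps * (n_snps - 1) // 2


PAIR_DTYPE = np.dtype(
    [
        ("i", np.int64),
        ("j", np.int64),
        ("rho_case", np.float64),
        ("rho_control", np.float64),
        ("rho_diff", np.float64),
        ("n_case_used", np.int64),
        ("n_ctrl_used", np.int64),
        ("valid", np.bool_),
    ]
)


def _group_count_arrays(g: np.ndarray, group_mask: np.ndarray):
    """Precompute per-group indicator matrices used by the block scan.

    Returns (obs, xval, xsq): int64 arrays of shape (n_snps, n_group) with
    the observed mask, encoded value (0 where unobserved), and squared
    encoded value.  All downstream tallies are exact integer dot products.
    """
    sub = g[:, group_mask]
    obs = (sub != MISSING).astype(np.int64)
    val = np.where(sub != MISSING, sub.astype(np.int64) - 1, 0)
    return obs, val, val * val


def _score_block(arrs_case, arrs_ctrl, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Score the pair block rows x cols; returns a PAIR_DTYPE record array.

    Only entries with row index < col index are emitted.  For each group the
    statistic reduces to exact counts: with S_xy = sum over complete pairs of
    x*y, S_xx = sum of x^2 over the pair-complete set (and S_yy likewise),
    rho = S_xy / sqrt(S_xx * S_yy).
    """
    def _tallies(arrs):
        obs, val, sq = arrs
        o_r, v_r, s_r = obs[rows], val[rows], sq[rows]
        o_c, v_c, s_c = obs[cols], val[cols], sq[cols]
        # n_used, S_xy, S_xx, S_yy — all exact int64 dot products
        return o_r @ o_c.T, v_r @ v_c.T, s_r @ o_c.T, o_r @ s_c.T

    n_ca, xy_ca, xx_ca, yy_ca = _tallies(arrs_case)
    n_co, xy_co, xx_co, yy_co = _tallies(arrs_ctrl)

    ri, ci = np.meshgrid(rows, cols, indexing="ij")
    upper = ri < ci
    ii, jj = ri[upper], ci[upper]

    def _rho_flat(xy, xx, yy):
        xx_f, yy_f, xy_f = (a[upper].astype(np.float64) for a in (xx, yy, xy))
        den = np.sqrt(xx_f * yy_f)
        ok = den > 0
        out = np.full(xy_f.shape, np.nan)
        out[ok] = xy_f[ok] / den[ok]
        return out, ok

    r_case, ok_case = _rho_flat(xy_ca, xx_ca, yy_ca)
    r_ctrl, ok_ctrl = _rho_flat(xy_co, xx_co, yy_co)
    valid = ok_case & ok_ctrl & (n_ca[upper] > 0) & (n_co[upper] > 0)

    rec = np.empty(ii.size, dtype=PAIR_DTYPE)
    rec["i"], rec["j"] = ii, jj
    rec["rho_case"], rec["rho_control"] = r_case, r_ctrl
    rec["rho_diff"] = np.where(valid, np.abs(r_ctrl - r_case), np.nan)
    rec["n_case_used"] = n_ca[upper]
    rec["n_ctrl_used"] = n_co[upper]
    rec["valid"] = valid
    return rec


def scan_to_records(
    gm: GenotypeMatrix,
    labels: PhenotypeLabels,
    chunk_size: int = 10_000,
    workers: int = 1,
) -> np.ndarray:
    """Exhaustive pair scan; returns one PAIR_DTYPE record per unordered pair.

    The SNP index range is split into blocks of at most ``chunk_size``;
    block pairs (bi <= bj) are scored independently — in parallel when
    ``workers > 1`` — and concatenated in deterministic block order.  Scores
    are bit-identical across chunk sizes and worker counts because every
    tally is an exact integer sum.
    """
    labels.check_aligned(gm)
    n = gm.n_snps
    if n < 2:
        raise ValueError("need at least two SNPs")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    g = gm.genotypes
    arrs_case = _group_count_arrays(g, labels.case_mask)
    arrs_ctrl = _group_count_arrays(g, labels.control_mask)

    starts = list(range(0, n, chunk_size))
    blocks = [
        (np.arange(a, min(a + chunk_size, n)), np.arange(b, min(b + chunk_size, n)))
        for ai, a in enumerate(starts)
        for b in starts[ai:]
    ]
    if workers > 1:
        parts = Parallel(n_jobs=workers, prefer="threads")(
            delayed(_score_block)(arrs_case, arrs_ctrl, rows, cols) for rows, cols in blocks
        )
    else:
        parts = [_score_block(arrs_case, arrs_ctrl, rows, cols) for rows, cols in blocks]
    out = np.concatenate(parts)
    assert out.size == pair_count(n)
    return out


def all_pairs_scan(
    gm: GenotypeMatrix,
    labels: PhenotypeLabels,
    chunk_size: int = 10_000,
    workers: int = 1,
) -> Iterator[PairScore]:
    """Stream PairScore objects for all N(N-1)/2 pairs (thin view over the scan)."""
    for rec in scan_to_records(gm, labels, chunk_size=chunk_size, workers=workers):
        yield PairScore(
            i=int(rec["i"]),
            j=int(rec["j"]),
            rho_case=float(rec["rho_case"]),
            rho_control=float(rec["rho_control"]),
            rho_diff=float(rec["rho_diff"]),
            n_case_used=int(rec["n_case_used"]),
            n_ctrl_used=int(rec["n_ctrl_used"]),
            valid=bool(rec["valid"]),
        )
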