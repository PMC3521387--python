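"""Case/control GWAS simulator driven by multi-locus penetrance models.

Each simulated individual is an independent genotype vector: every locus is
drawn under Hardy-Weinberg equilibrium from its minor (variant) allele
frequency q — genotype probabilities (1-q)^2, 2q(1-q), q^2 for w, h, v —
and background loci get MAFs drawn uniformly from a configurable range.
Disease status is Bernoulli with probability given by the penetrance table
at the individual's genotypes at the disease loci.  Rejection sampling
continues until exactly ``n_case`` cases and ``n_control`` controls are
accumulated; surplus individuals of a filled class are discarded.

Multi-locus models come in two flavors: an explicit L-locus penetrance
table (3^L entries), or an interaction network of pairwise (2-locus) tables
over named loci, composed into a joint table by either a heterogeneity rule
(independent disease routes, 1 - prod(1 - p_edge)) or a multiplicative
rule (prod(p_edge), rescaled so the largest cell is the largest edge-product
value mapped into [0, 1]).

No linkage disequilibrium, population structure, or genotyping error is
simulated: background loci are mutually independent, so any pairwise
dependence contrast at non-disease pairs is pure sampling noise.

The package ships small example model-spec files (see ``iloci/models/``);
these are synthetic reconstructions of classic two-locus model families,
not verbatim published tables.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, PhenotypeLabels

__all__ = [
    "PenetranceModel",
    "InteractionNetwork",
    "SimConfig",
    "ModelSpecError",
    "load_model_spec",
    "save_model_spec",
    "compose_network_model",
    "analytic_prevalence",
    "simulate_population",
    "simulate_dataset",
    "default_disease_positions",
]

ATTEMPT_BUDGET = 100_000_000  # individual draws before giving up
_BATCH = 4096


class ModelSpecError(ValueError):
    """Raised for malformed or invalid model specification files."""


@dataclass
class PenetranceModel:
    """L-locus disease model: per-locus MAFs and a 3^L penetrance table.

    ``table`` has shape (3,)*L indexed by genotype code (0=w, 1=h, 2=v) at
    each locus, locus 1 on axis 0.  ``h2`` is a nominal heritability label
    carried as metadata only.
    """

    mafs: np.ndarray
    table: np.ndarray
    label: str = ""
    h2: str | None = None
    true_pairs: list[tuple[int, int]] | None = None  # locus-index pairs, if composed

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=np.float64)
        self.table = np.asarray(self.table, dtype=np.float64)
        L = self.mafs.size
        if self.table.shape != (3,) * L:
            raise ModelSpecError(
                f"penetrance table must have 3^{L} entries, got shape {self.table.shape}"
            )
        if ((self.mafs <= 0) | (self.mafs > 0.5)).any():
            raise ModelSpecError("MAFs must lie in (0, 0.5]")
        bad = np.argwhere((self.table < 0) | (self.table > 1))
        if bad.size:
            cell = tuple(int(v) for v in bad[0])
            raise ModelSpecError(
                f"penetrance out of [0,1] at cell {cell}: {self.table[cell]}"
            )

    @property
    def L(self) -> int:
        return self.mafs.size


@dataclass
class InteractionNetwork:
    """Pairwise-interaction network: named loci plus 2-locus edge tables."""

    node_names: list[str]
    node_mafs: np.ndarray
    edges: list[tuple[int, int, np.ndarray]]  # (node_a, node_b, 3x3 table)
    combine: str = "heterogeneity"
    label: str = ""
    h2: str | None = None

    def __post_init__(self) -> None:
        self.node_mafs = np.asarray(self.node_mafs, dtype=np.float64)
        if self.combine not in ("heterogeneity", "multiplicative"):
            raise ModelSpecError(f"unknown combine rule {self.combine!r}")
        if not self.edges:
            raise ModelSpecError("network must have at least one edge")
        n = len(self.node_names)
        for a, b, t in self.edges:
            if not (0 <= a < n and 0 <= b < n and a != b):
                raise ModelSpecError(f"edge ({a},{b}) endpoints not declared nodes")
            t = np.asarray(t)
            if t.shape != (3, 3) or ((t < 0) | (t > 1)).any():
                raise ModelSpecError(f"edge ({a},{b}) table must be 3x3 in [0,1]")

    @property
    def L(self) -> int:
        return len(self.node_names)


def compose_network_model(net: InteractionNetwork) -> PenetranceModel:
    """Collapse a pairwise network into a joint L-locus penetrance table.

    heterogeneity: pen(g) = 1 - prod_edges (1 - pen_edge(g_a, g_b)) — each
    edge is an independent route to disease; an all-zero edge contributes
    nothing.  multiplicative: pen(g) = prod_edges pen_edge(g_a, g_b),
    rescaled by its maximum into [0, 1] (zero table if all products vanish).
    """
    L = net.L
    if L > 6:
        raise ModelSpecError("network composition limited to 6 loci (3^L table)")
    table = np.empty((3,) * L)
    for g in itertools.product(range(3), repeat=L):
        if net.combine == "heterogeneity":
            pen = 1.0
            for a, b, t in net.edges:
                pen *= 1.0 - t[g[a], g[b]]
            table[g] = 1.0 - pen
        else:
            pen = 1.0
            for a, b, t in net.edges:
                pen *= t[g[a], g[b]]
            table[g] = pen
    if net.combine == "multiplicative":
        m = table.max()
        if m > 0:
            table = table / m
    true_pairs = sorted({(min(a, b), max(a, b)) for a, b, _ in net.edges})
    return PenetranceModel(
        mafs=net.node_mafs.copy(),
        table=table,
        label=net.label or "composed-network",
        h2=net.h2,
        true_pairs=true_pairs,
    )


# ---------------------------------------------------------------------------
# model spec files
#
# Key-value header lines ("key: value"), then numeric table lines.  A model:
#     type: model / L / mafs / label / h2 / table: <3^L numbers, odometer
#     order over {w,h,v}^L with locus 1 slowest>
# A network adds node/edge declarations:
#     type: network / combine / node: NAME MAF / edge: NAME NAME <9 numbers>
# "#" lines are comments.
# ---------------------------------------------------------------------------


def load_model_spec(path) -> PenetranceModel | InteractionNetwork:
    """Parse a model spec file into a PenetranceModel or InteractionNetwork."""
    header: dict[str, str] = {}
    numbers: list[float] = []
    nodes: list[tuple[str, float]] = []
    edges: list[tuple[str, str, list[float]]] = []
    current_edge: list[float] | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line and not _is_numeric_line(line):
                key, _, value = line.partition(":")
                key = key.strip().lower()
                value = value.strip()
                if key == "node":
                    name, maf = value.split()
                    nodes.append((name, float(maf)))
                    current_edge = None
                elif key == "edge":
                    parts = value.split()
                    current_edge = [float(x) for x in parts[2:]]
                    edges.append((parts[0], parts[1], current_edge))
                elif key == "table":
                    current_edge = None
                    numbers.extend(float(x) for x in value.split())
                else:
                    header[key] = value
                    current_edge = None
            else:
                vals = [float(x) for x in line.split()]
                if current_edge is not None:
                    current_edge.extend(vals)
                else:
                    numbers.extend(vals)

    kind = header.get("type", "model")
    label = header.get("label", "")
    h2 = header.get("h2")
    if kind == "network":
        if not nodes:
            raise ModelSpecError(f"{path}: network spec has no nodes")
        name_idx = {name: i for i, (name, _) in enumerate(nodes)}
        built_edges = []
        for a, b, vals in edges:
            if a not in name_idx or b not in name_idx:
                raise ModelSpecError(f"{path}: edge references unknown node {a} or {b}")
            if len(vals) != 9:
                raise ModelSpecError(
                    f"{path}: edge {a}-{b}: expected 9 entries, got {len(vals)}"
                )
            built_edges.append(
                (name_idx[a], name_idx[b], np.array(vals).reshape(3, 3))
            )
        return InteractionNetwork(
            node_names=[n for n, _ in nodes],
            node_mafs=np.array([m for _, m in nodes]),
            edges=built_edges,
            combine=header.get("combine", "heterogeneity"),
            label=label,
            h2=h2,
        )

    if "mafs" not in header:
        raise ModelSpecError(f"{path}: model spec missing 'mafs'")
    mafs = np.array([float(x) for x in header["mafs"].split()])
    L = int(header.get("l", mafs.size))
    if L != mafs.size:
        raise ModelSpecError(f"{path}: L={L} but {mafs.size} MAFs given")
    if len(numbers) != 3**L:
        raise ModelSpecError(
            f"{path}: expected {3 ** L} penetrance entries, got {len(numbers)}"
        )
    table = np.array(numbers).reshape((3,) * L)
    return PenetranceModel(mafs=mafs, table=table, label=label, h2=h2)


def _is_numeric_line(line: str) -> bool:
    try:
        [float(x) for x in line.split()]
        return True
    except ValueError:
        return False


def save_model_spec(model: PenetranceModel, path) -> None:
    """Write a PenetranceModel as a spec file (lossless via repr floats)."""
    with open(path, "w") as fh:
        fh.write("type: model\n")
        fh.write(f"L: {model.L}\n")
        fh.write("mafs: " + " ".join(repr(float(m)) for m in model.mafs) + "\n")
        if model.label:
            fh.write(f"label: {model.label}\n")
        if model.h2 is not None:
            fh.write(f"h2: {model.h2}\n")
        fh.write("table:\n")
        flat = model.table.reshape(-1)
        per_line = 9 if model.L >= 2 else 3
        for start in range(0, flat.size, per_line):
            fh.write(" ".join(repr(float(v)) for v in flat[start:start + per_line]) + "\n")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Dataset-level simulation parameters."""

    n_case: int = 800
    n_control: int = 800
    n_snps: int = 100
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    disease_locus_positions: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")
        lo, hi = self.background_maf_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi <= 0.5)):
            raise ValueError("background MAF range must lie within (0, 0.5]")


def default_disease_positions(n_snps: int, L: int) -> list[int]:
    """Evenly spaced disease-locus indices, e.g. 2 loci in 100 SNPs -> 33, 66."""
    return [((k + 1) * n_snps) // (L + 1) for k in range(L)]


def analytic_prevalence(model: PenetranceModel) -> float:
    """Population disease prevalence: sum over genotype cells of HWE prob x penetrance."""
    prev = 0.0
    for g in itertools.product(range(3), repeat=model.L):
        p = 1.0
        for locus, code in enumerate(g):
            q = model.mafs[locus]
            p *= ((1 - q) ** 2, 2 * q * (1 - q), q**2)[code]
        prev += p * model.table[g]
    return prev


def _draw_hwe_genotypes(rng: np.random.Generator, qs: np.ndarray, n: int) -> np.ndarray:
    """Draw n individuals x len(qs) loci of HWE genotype codes {0,1,2}."""
    u = rng.random((n, qs.size))
    thr_w = (1 - qs) ** 2
    thr_h = thr_w + 2 * qs * (1 - qs)
    return ((u >= thr_w).astype(np.int8) + (u >= thr_h).astype(np.int8))


def simulate_population(
    model: PenetranceModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n unconditioned individuals at the disease loci only.

    Returns (genotypes of shape (n, L), disease status bool array).  Used
    for prevalence calibration; no background SNPs, no rejection.
    """
    g = _draw_hwe_genotypes(rng, model.mafs, n)
    pen = model.table[tuple(g.T)]
    status = rng.random(n) < pen
    return g, status


def simulate_dataset(
    model: PenetranceModel | InteractionNetwork, cfg: SimConfig
) -> tuple[GenotypeMatrix, PhenotypeLabels, dict]:
    """Simulate a case/control dataset with the model's loci embedded.

    Rejection-samples independent individuals until the case and control
    quotas are both filled; raises if the budget of draws is exhausted
    (e.g. all-zero penetrance makes cases unreachable).  Returns the
    genotype matrix (cases first), labels, and a truth record listing the
    disease locus indices and true interacting pairs.
    """
    network = isinstance(model, InteractionNetwork)
    pmodel = compose_network_model(model) if network else model
    if pmodel.table.max() == 0:
        raise ValueError("all penetrances are 0: cases unreachable")
    if pmodel.table.min() == 1:
        raise ValueError("all penetrances are 1: controls unreachable")
    L = pmodel.L
    if cfg.n_snps < L:
        raise ValueError(f"n_snps={cfg.n_snps} < {L} disease loci")
    positions = cfg.disease_locus_positions or default_disease_positions(cfg.n_snps, L)
    if len(set(positions)) != L or any(not 0 <= p < cfg.n_snps for p in positions):
        raise ValueError("disease locus positions must be distinct and in range")

    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.background_maf_range
    qs = rng.uniform(lo, hi, cfg.n_snps)
    qs[positions] = pmodel.mafs

    need_case, need_ctrl = cfg.n_case, cfg.n_control
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    drawn = 0
    while need_case > 0 or need_ctrl > 0:
        if drawn >= ATTEMPT_BUDGET:
            raise RuntimeError(
                f"attempt budget exhausted after {drawn} draws "
                f"({cfg.n_case - need_case}/{cfg.n_case} cases, "
                f"{cfg.n_control - need_ctrl}/{cfg.n_control} controls)"
            )
        g = _draw_hwe_genotypes(rng, qs, _BATCH)
        drawn += _BATCH
        pen = pmodel.table[tuple(g[:, positions].T)]
        is_case = rng.random(_BATCH) < pen
        if need_case > 0:
            take = g[is_case][:need_case]
            cases.append(take)
            need_case -= take.shape[0]
        if need_ctrl > 0:
            take = g[~is_case][:need_ctrl]
            ctrls.append(take)
            need_ctrl -= take.shape[0]

    geno = np.vstack([np.vstack(cases), np.vstack(ctrls)]).T.astype(np.int8)
    n_total = cfg.n_case + cfg.n_control
    width = len(str(n_total))
    sample_ids = [f"ind{k + 1:0{width}d}" for k in range(n_total)]
    status = np.zeros(n_total, dtype=bool)
    status[: cfg.n_case] = True
    snp_width = len(str(cfg.n_snps))
    gm = GenotypeMatrix(
        snp_ids=[f"snp{k + 1:0{snp_width}d}" for k in range(cfg.n_snps)],
        chrom=["1"] * cfg.n_snps,
        pos=np.arange(cfg.n_snps, dtype=np.int64) * 10_000 + 1_000,
        alleles=[("A", "G")] * cfg.n_snps,
        genotypes=geno,
        sample_ids=sample_ids,
    )
    labels = PhenotypeLabels(sample_ids, status)

    if network or pmodel.true_pairs is not None:
        locus_pairs = pmodel.true_pairs or []
        scenario = "higher_order"
    elif L == 2:
        locus_pairs = [(0, 1)]
        scenario = "single_pair"
    else:
        locus_pairs = [(a, b) for a in range(L) for b in range(a + 1, L)]
        scenario = "multi_pair"
    truth = {
        "disease_snp_indices": sorted(positions),
        "true_pairs": sorted(
            tuple(sorted((positions[a], positions[b]))) for a, b in locus_pairs
        ),
        "scenario": scenario,
        "model_label": pmodel.label,
        "seed": cfg.seed,
        "analytic_prevalence": analytic_prevalence(pmodel),
        "snp_ids": gm.snp_ids,
    }
    return gm, labels, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path) as fh:
        truth = json.load(fh)
    truth["true_pairs"] = [tuple(p) for p in truth["true_pairs"]]
    return truth
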