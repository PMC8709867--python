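"""MG94xHKY codon substitution model with branch-category dN/dS estimation.

The model lives on the 61 sense codons of the standard nuclear code.  An
instantaneous change between codons differing at exactly one nucleotide has
rate proportional to the target codon frequency pi_j, multiplied by kappa for
transitions and by the category's omega for nonsynonymous changes;
multi-nucleotide changes have rate 0.  Every built matrix is normalized to
unit expected substitution rate, so branch lengths are expected substitutions
per codon, as in codeml's branch models.

Likelihoods are computed by Felsenstein pruning with per-site scaling; the
reversible structure is exploited through a symmetric eigendecomposition so
that all branch transition matrices of a category come from one ``eigh``.
Branch lengths can be optimized freely, or constrained to a synonymous
molecular clock ("clock" mode): one synonymous rate per MY shared by all
branches, with each branch's total length scaled up by its category's
nonsynonymous load.  Clock mode cuts the parameter count to
(rate, kappa, one omega per category), which is what makes simulation-based
calibration of the downstream dating affordable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from Bio.Data.CodonTable import standard_dna_table

from genedecay.event_inference import StatusTree

NUCS = "TCAG"
CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(p) for p in itertools.product(NUCS, repeat=3))
    if c not in standard_dna_table.stop_codons
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61
MISSING = -1

_AA = {c: standard_dna_table.forward_table[c] for c in CODONS}
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 tables: single-nucleotide change, transition, synonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, a in enumerate(CODONS):
        for j, b in enumerate(CODONS):
            if i == j:
                continue
            diff = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diff) != 1:
                continue
            single[i, j] = True
            transition[i, j] = frozenset(diff[0]) in _TRANSITIONS
            synonymous[i, j] = _AA[a] == _AA[b]
    return single, transition, synonymous

SINGLE_STEP, IS_TRANSITION, IS_SYNONYMOUS = _pair_tables()


@dataclass
class CodonModelParams:
    """MG94xHKY parameters: kappa, per-category omega, codon frequencies,
    and per-branch lengths in expected substitutions per codon."""

    kappa: float
    omega_by_category: dict
    pi: np.ndarray
    branch_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0 or any(w <= 0 for w in self.omega_by_category.values()):
            raise ValueError("kappa and all omegas must be positive")
        if self.pi.shape != (N_CODONS,) or np.any(self.pi <= 0):
            raise ValueError("pi must be a strictly positive vector over 61 codons")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")


@dataclass
class LRTResult:
    """Likelihood-ratio test of relaxed selection on foreground branches."""

    lnl_null: float
    lnl_alt: float
    statistic: float
    df: int
    pvalue: float
    omega_null: float
    omega_foreground: float
    omega_background: float
    # auxiliary test: foreground omega fixed at 1 vs free
    aux_statistic: float | None = None
    aux_pvalue: float | None = None


class CodonAlignment:
    """Gap-aware codon matrix over the 61 sense codons.

    Rows flagged pseudogenic may contain in-frame stop codons; these are
    recoded as missing for likelihood purposes.  Stops in functional rows are
    an error.  Gaps and ambiguous codons are missing data.
    """

    def __init__(self, taxa: Sequence[str], codes: np.ndarray,
                 pseudogenic: frozenset = frozenset()):
        self.taxa = list(taxa)
        self.codes = np.asarray(codes, dtype=np.int16)
        self.pseudogenic = frozenset(pseudogenic)
        if self.codes.shape[0] != len(self.taxa):
            raise ValueError("one row per taxon required")

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(
        cls, sequences: Mapping[str, str], pseudogenic: Iterable[str] = ()
    ) -> "CodonAlignment":
        pseudogenic = frozenset(pseudogenic)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("all rows must have equal length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length must be a multiple of 3")
        taxa = list(sequences)
        codes = np.full((len(taxa), length // 3), MISSING, dtype=np.int16)
        for row, taxon in enumerate(taxa):
            seq = sequences[taxon].upper()
            for site in range(length // 3):
                codon = seq[3 * site : 3 * site + 3]
                idx = CODON_INDEX.get(codon)
                if idx is None:
                    if codon in standard_dna_table.stop_codons and taxon not in pseudogenic:
                        raise ValueError(
                            f"in-frame stop {codon} at codon site {site + 1} in "
                            f"functional row {taxon!r}"
                        )
                    idx = MISSING  # gap, ambiguity, or recoded stop
                codes[row, site] = idx
        return cls(taxa, codes, pseudogenic)

    def empirical_pi(self, mode: str = "f3x4") -> np.ndarray:
        return empirical_pi(self, mode)


def empirical_pi(aln: CodonAlignment, mode: str = "f3x4") -> np.ndarray:
    """Codon frequencies: equal, F1x4 or F3x4 (products renormalized over the
    61 sense codons, with a small floor to keep every codon reachable)."""
    if mode == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    counts_by_pos = np.ones((3, 4))  # +1 pseudocount per nucleotide and position
    for row in range(aln.codes.shape[0]):
        for code in aln.codes[row]:
            if code == MISSING:
                continue
            for pos, nuc in enumerate(CODONS[code]):
                counts_by_pos[pos, NUCS.index(nuc)] += 1
    if mode == "f1x4":
        freq = counts_by_pos.sum(axis=0)
        freq = freq / freq.sum()
        nuc_freqs = np.vstack([freq] * 3)
    elif mode == "f3x4":
        nuc_freqs = counts_by_pos / counts_by_pos.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown pi mode {mode!r}")
    pi = np.array(
        [
            nuc_freqs[0, NUCS.index(c[0])]
            * nuc_freqs[1, NUCS.index(c[1])]
            * nuc_freqs[2, NUCS.index(c[2])]
            for c in CODONS
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------


def _raw_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    rate = np.where(SINGLE_STEP, pi[np.newaxis, :], 0.0)
    rate = np.where(SINGLE_STEP & IS_TRANSITION, rate * kappa, rate)
    rate = np.where(SINGLE_STEP & ~IS_SYNONYMOUS, rate * omega, rate)
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    return rate


def syn_nonsyn_potentials(pi: np.ndarray, kappa: float) -> tuple[float, float]:
    """Expected synonymous and nonsynonymous flux of the unnormalized model at
    omega = 1: S = sum_i pi_i sum_{j syn} pi_j kappa^ts, N likewise."""
    base = np.where(SINGLE_STEP, pi[np.newaxis, :], 0.0)
    base = np.where(SINGLE_STEP & IS_TRANSITION, base * kappa, base)
    syn = float(pi @ np.where(IS_SYNONYMOUS, base, 0.0).sum(axis=1))
    nonsyn = float(pi @ np.where(SINGLE_STEP & ~IS_SYNONYMOUS, base, 0.0).sum(axis=1))
    return syn, nonsyn


def build_rate_matrix(params: CodonModelParams, category) -> np.ndarray:
    """Normalized MG94xHKY rate matrix for one omega category.

    Rows sum to zero, the expected substitution rate is 1, and detailed
    balance pi_i q_ij = pi_j q_ji holds.
    """
    omega = params.omega_by_category[category]
    raw = _raw_rate_matrix(params.pi, params.kappa, omega)
    rate = float(params.pi @ -np.diag(raw))
    return raw / rate


def _eigensystem(pi: np.ndarray, q: np.ndarray):
    """Symmetric eigendecomposition of a reversible rate matrix."""
    sqrt_pi = np.sqrt(pi)
    sym = (q * sqrt_pi[np.newaxis, :]) / sqrt_pi[:, np.newaxis]
    eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
    eigval = np.minimum(eigval, 0.0)  # generator spectra are non-positive
    left = eigvec.T * sqrt_pi[np.newaxis, :]        # U^T D^{1/2}
    right = eigvec / sqrt_pi[:, np.newaxis]         # D^{-1/2} U
    return eigval, right, left


def transition_matrix(eigensystem, t: float) -> np.ndarray:
    eigval, right, left = eigensystem
    p = (right * np.exp(eigval * t)[np.newaxis, :]) @ left
    return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


class _PrunedTree:
    """Flattened postorder view of a StatusTree for fast repeated pruning."""

    def __init__(self, tree: StatusTree, taxa: Sequence[str]):
        dtree = tree.dendropy_tree
        taxon_row = {name: i for i, name in enumerate(taxa)}
        self.postorder: list = []
        self.branch_keys: list = []
        node_ids: dict = {}
        for node in dtree.postorder_node_iter():
            node_ids[id(node)] = len(node_ids)
            if node.is_leaf():
                label = node.taxon.label
                if label not in taxon_row:
                    raise ValueError(f"leaf {label!r} absent from alignment")
                self.postorder.append(("leaf", id(node), taxon_row[label]))
            else:
                children = [id(c) for c in node.child_nodes()]
                self.postorder.append(("internal", id(node), children))
            if node.parent_node is not None:
                self.branch_keys.append((id(node), tree.branch_key(node)))
        self.root_id = id(dtree.seed_node)
        self.branch_key_by_node = dict(self.branch_keys)
        if len(taxa) != sum(1 for e in self.postorder if e[0] == "leaf"):
            raise ValueError("alignment taxa and tree leaves must coincide")


def log_likelihood(
    tree: StatusTree,
    aln: CodonAlignment,
    params: CodonModelParams,
    category_map: Mapping | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of the alignment on the tree.

    ``category_map`` maps branch keys to omega categories; by default every
    branch uses the single category present in ``params``.  Missing data
    (gaps, recoded stops) contribute all-ones partials; the root is weighted
    by pi.
    """
    if category_map is None:
        if len(params.omega_by_category) != 1:
            raise ValueError("category_map required with multiple omega categories")
        only = next(iter(params.omega_by_category))
        category_map = {key: only for key in tree.labels}
    pruned = _PrunedTree(tree, aln.taxa)
    patterns, weights = _compress(aln.codes)
    lnl = _pruned_lnl(pruned, patterns, weights, params, category_map)
    if not np.isfinite(lnl):
        raise ValueError("non-finite log-likelihood")
    return float(lnl)


def _compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return patterns, weights.astype(float)


def _pruned_lnl(
    pruned: _PrunedTree,
    patterns: np.ndarray,
    weights: np.ndarray,
    params: CodonModelParams,
    category_map: Mapping,
) -> float:
    eigensystems = {
        cat: _eigensystem(params.pi, build_rate_matrix(params, cat))
        for cat in set(category_map.values())
    }
    n_pat = patterns.shape[1]
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_pat)
    transition: dict[int, np.ndarray] = {}
    for node_id, key in pruned.branch_key_by_node.items():
        cat = category_map[key]
        t = params.branch_lengths[key]
        if t < 0:
            raise ValueError("negative branch length")
        transition[node_id] = transition_matrix(eigensystems[cat], t)

    for entry in pruned.postorder:
        kind, node_id, payload = entry
        if kind == "leaf":
            row = patterns[payload]
            p = transition[node_id]
            msg = np.ones((N_CODONS, n_pat))
            observed = row != MISSING
            msg[:, observed] = p[:, row[observed]]
            partials[node_id] = msg
        else:
            prod = np.ones((N_CODONS, n_pat))
            for child in payload:
                prod *= partials.pop(child)
            scale = prod.max(axis=0)
            scale[scale == 0.0] = 1.0
            prod /= scale
            log_scale += np.log(scale)
            if node_id == pruned.root_id:
                partials[node_id] = prod
            else:
                partials[node_id] = transition[node_id] @ prod
    site_lik = params.pi @ partials[pruned.root_id]
    good = np.isfinite(site_lik) & (site_lik > 0)
    if not good.all():
        bad = int(np.argmax(~good))
        raise ValueError(f"zero or non-finite site likelihood at pattern {bad}")
    return float(weights @ (np.log(site_lik) + log_scale))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: CodonModelParams
    lnl: float
    converged: bool
    n_evaluations: int
    lengths_mode: str


_OMEGA_GRID = (0.1, 0.5, 1.5)
_KAPPA_GRID = (1.0, 2.0, 5.0)


def fit(
    tree: StatusTree,
    aln: CodonAlignment,
    category_map: Mapping,
    *,
    pi_mode: str = "f3x4",
    lengths_mode: str = "clock",
    fixed_omega: Mapping | None = None,
    fixed_kappa: float | None = None,
    restarts: int = 5,
    tol: float = 1e-6,
) -> FitResult:
    """Maximize the likelihood over kappa, category omegas and branch lengths.

    ``lengths_mode='clock'`` ties branch lengths to the time tree through a
    single synonymous rate per MY (each branch's total length is its
    category's nonsynonymous load times that rate); ``'free'`` optimizes every
    branch length.  ``fixed_omega`` pins named categories (e.g. foreground
    omega = 1 for the auxiliary relaxation test).  Optimization is bounded
    quasi-Newton (L-BFGS-B) on log-parameters from the best point of a small
    (kappa, omega) starting grid; deterministic throughout.
    """
    if lengths_mode not in ("clock", "free"):
        raise ValueError("lengths_mode must be 'clock' or 'free'")
    fixed_omega = dict(fixed_omega or {})
    pi = empirical_pi(aln, pi_mode)
    categories = sorted(set(category_map.values()))
    free_cats = [c for c in categories if c not in fixed_omega]
    branch_keys = sorted(category_map, key=sorted)
    durations = {key: tree.branch_duration(key) for key in branch_keys}
    pruned = _PrunedTree(tree, aln.taxa)
    patterns, weights = _compress(aln.codes)

    # crude divergence-based starting rate: mean pairwise codon mismatch
    p_dist = _mean_pairwise_distance(aln)
    depth = max(tree.root_age, 1e-6)
    mu0 = max(p_dist / (2.0 * depth), 1e-5)

    def unpack(theta: np.ndarray) -> tuple[CodonModelParams, Mapping]:
        pos = 0
        if fixed_kappa is None:
            kappa = float(np.exp(theta[pos])); pos += 1
        else:
            kappa = fixed_kappa
        omegas = dict(fixed_omega)
        for cat in free_cats:
            omegas[cat] = float(np.exp(theta[pos])); pos += 1
        syn, nonsyn = syn_nonsyn_potentials(pi, kappa)
        lengths = {}
        if lengths_mode == "clock":
            mu = float(np.exp(theta[pos])); pos += 1
            for key in branch_keys:
                w = omegas[category_map[key]]
                load = (syn + w * nonsyn) / syn
                lengths[key] = mu * durations[key] * load
        else:
            for key in branch_keys:
                lengths[key] = float(np.exp(theta[pos])); pos += 1
        params = CodonModelParams(
            kappa=kappa, omega_by_category=omegas, pi=pi, branch_lengths=lengths
        )
        return params, category_map

    evaluations = 0

    def objective(theta: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        params, cmap = unpack(theta)
        try:
            val = -_pruned_lnl(pruned, patterns, weights, params, cmap)
        except (ValueError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    def pack(kappa: float, omega: float, mu: float) -> np.ndarray:
        theta = []
        if fixed_kappa is None:
            theta.append(np.log(kappa))
        theta.extend(np.log(omega) for _ in free_cats)
        if lengths_mode == "clock":
            theta.append(np.log(mu))
        else:
            for key in branch_keys:
                theta.append(np.log(max(mu * durations[key], 1e-6)))
        return np.array(theta)

    # starting grid: evaluate, keep the best point
    best_start, best_val = None, np.inf
    kappas = _KAPPA_GRID if fixed_kappa is None else (fixed_kappa,)
    for kappa in kappas:
        for omega in _OMEGA_GRID:
            theta = pack(kappa, omega, mu0)
            val = objective(theta)
            if val < best_val:
                best_start, best_val = theta, val

    n = len(best_start)
    bounds = []
    if fixed_kappa is None:
        bounds.append((np.log(0.05), np.log(100.0)))
    bounds.extend([(np.log(1e-4), np.log(20.0))] * len(free_cats))
    if lengths_mode == "clock":
        bounds.append((np.log(1e-8), np.log(10.0)))  # syn subs/codon/MY
    else:
        bounds.extend([(np.log(1e-8), np.log(20.0))] * len(branch_keys))
    result = None
    rng = np.random.default_rng(0)
    for attempt in range(max(restarts, 1)):
        start = best_start if attempt == 0 else best_start + rng.normal(0, 0.3, n)
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-6, "maxiter": 500},
        )
        if result is None or res.fun < result.fun:
            result = res
        if result.success:
            break
    params, _ = unpack(result.x)
    if not result.success and result.fun >= 1e11:
        raise RuntimeError("codon model optimization failed to find a finite optimum")
    return FitResult(
        params=params,
        lnl=-float(result.fun),
        converged=bool(result.success),
        n_evaluations=evaluations,
        lengths_mode=lengths_mode,
    )


def _mean_pairwise_distance(aln: CodonAlignment) -> float:
    codes = aln.codes
    n = codes.shape[0]
    if n < 2:
        return 0.05
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] != MISSING) & (codes[j] != MISSING)
            if both.sum():
                total += np.mean(codes[i][both] != codes[j][both])
                count += 1
    return total / max(count, 1) or 0.05


# ---------------------------------------------------------------------------
# tests of relaxed selection
# ---------------------------------------------------------------------------


def lrt_relaxation(
    tree: StatusTree,
    aln: CodonAlignment,
    foreground: Iterable,
    *,
    pi_mode: str = "f3x4",
    lengths_mode: str = "clock",
    boundary_mixture: bool = False,
    aux: bool = True,
) -> LRTResult:
    """LRT of a separate foreground omega against one shared omega (df = 1).

    ``aux`` additionally runs the test of foreground omega fixed at 1 against
    free.  ``boundary_mixture`` switches the null distribution to the 50:50
    chi2(0):chi2(1) mixture (off by default).
    """
    foreground = {frozenset(b) for b in foreground}
    all_branches = set(tree.labels)
    if not foreground:
        raise ValueError("foreground must be non-empty")
    if not foreground <= all_branches:
        raise ValueError("foreground branches not in tree")
    if foreground == all_branches:
        raise ValueError("foreground must be a proper subset of branches")

    null_map = {key: "all" for key in all_branches}
    alt_map = {
        key: ("fg" if key in foreground else "bg") for key in all_branches
    }
    null_fit = fit(tree, aln, null_map, pi_mode=pi_mode, lengths_mode=lengths_mode)
    alt_fit = fit(tree, aln, alt_map, pi_mode=pi_mode, lengths_mode=lengths_mode)
    stat = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if stat < -1e-6:
        raise RuntimeError(f"negative LRT statistic {stat}; optimizer failure")
    stat = max(stat, 0.0)
    pvalue = float(chi2.sf(stat, df=1))
    if boundary_mixture:
        pvalue = 0.5 * pvalue if stat > 0 else 1.0

    aux_stat = None
    if aux:
        fixed_fit = fit(
            tree, aln, alt_map, pi_mode=pi_mode, lengths_mode=lengths_mode,
            fixed_omega={"fg": 1.0},
        )
        aux_stat = max(2.0 * (alt_fit.lnl - fixed_fit.lnl), 0.0)
    return LRTResult(
        lnl_null=null_fit.lnl,
        lnl_alt=alt_fit.lnl,
        statistic=stat,
        df=1,
        pvalue=pvalue,
        omega_null=null_fit.params.omega_by_category["all"],
        omega_foreground=alt_fit.params.omega_by_category["fg"],
        omega_background=alt_fit.params.omega_by_category["bg"],
        aux_statistic=aux_stat,
        aux_pvalue=float(chi2.sf(aux_stat, df=1)) if aux_stat is not None else None,
    )


# ---------------------------------------------------------------------------
# branch-category omegas for dating
# ---------------------------------------------------------------------------


@dataclass
class BranchOmegaTable:
    omega_functional: float
    omega_mixed: dict  # mixed branch key -> omega
    kappa: float
    per_branch: dict  # branch key -> dict(category, omega, length, syn_subs, nonsyn_subs)
    lnl: float


def branch_omegas_for_dating(
    tree: StatusTree,
    aln: CodonAlignment,
    labels: Mapping | None = None,
    *,
    pi_mode: str = "f3x4",
    lengths_mode: str = "clock",
) -> BranchOmegaTable:
    """Fit pooled functional omega, per-mixed-branch omegas, and (when
    pseudogenic branches exist) a pooled pseudogenic omega.

    ``labels`` defaults to the labels carried by the tree.  The returned
    per-branch table reports each branch's fitted length decomposed into
    expected synonymous and nonsynonymous substitutions per codon, which is
    what the 2ds rate-ratio estimate consumes.
    """
    labels = dict(labels if labels is not None else tree.labels)
    if not any(lab == "functional" for lab in labels.values()):
        raise ValueError("no functional branches; pooled omega_f undefined")
    category_map = {}
    mixed_ids = {}
    for key, label in labels.items():
        if label == "mixed":
            name = f"mixed_{len(mixed_ids)}"
            mixed_ids[key] = name
            category_map[key] = name
        elif label == "pseudogenic":
            category_map[key] = "pseudogenic"
        else:
            category_map[key] = "functional"
    result = fit(tree, aln, category_map, pi_mode=pi_mode, lengths_mode=lengths_mode)
    params = result.params
    syn, nonsyn = syn_nonsyn_potentials(params.pi, params.kappa)
    per_branch = {}
    for key, cat in category_map.items():
        w = params.omega_by_category[cat]
        t = params.branch_lengths[key]
        syn_frac = syn / (syn + w * nonsyn)
        per_branch[key] = {
            "category": labels[key],
            "omega": w,
            "length": t,
            "syn_subs": t * syn_frac,
            "nonsyn_subs": t * (1.0 - syn_frac),
        }
    return BranchOmegaTable(
        omega_functional=params.omega_by_category["functional"],
        omega_mixed={key: params.omega_by_category[name] for key, name in mixed_ids.items()},
        kappa=params.kappa,
        per_branch=per_branch,
        lnl=result.lnl,
    )
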