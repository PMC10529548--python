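"""Fixed-topology Bayesian node dating.

Model: partitioned GTR+Γ(+I) likelihood via Felsenstein pruning; an
uncorrelated lognormal relaxed clock (iid branch-rate multipliers with real-
space mean 1, spread clock_sd, times a global clock rate in subs/site/Myr);
a Yule pure-birth prior over node ages; normal calibration priors on the
ages of named clades' MRCAs (the study convention is sd = 0.01 Myr,
effectively fixing a calibrated date); Metropolis-Hastings MCMC over node
ages, branch rates, substitution-model parameters and hyperparameters, with
the topology held fixed.

Declared prior normalisations (the ones a fixed-topology sampler needs, not
unique in the literature):
  Yule:        sum over internal nodes of (log lambda - lambda * age)
  branch rate: r ~ LogNormal(-sd^2/2, sd) so E[r] = 1
  hyperpriors: lambda ~ LogNormal(0, 2); clock_sd ~ Exponential(1);
               clock_rate ~ LogNormal(-3, 3); exchangeabilities iid
               LogNormal(0, 1.5); gamma_shape ~ Exponential(1);
               p_inv ~ Uniform(0, 1). Base frequencies are fixed empirical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import NucleotideSequence
from .mapping import encode
from .substmodel import GtrModel, SubstitutionModelParams
from .trees import Chronogram

_EPS_AGE = 1e-9


@dataclass
class Partition:
    name: str
    columns: np.ndarray
    model: SubstitutionModelParams


@dataclass
class Calibration:
    """Normal prior on the age of the MRCA of a clade."""

    clade: frozenset
    mean_age: float
    sd: float

    def __post_init__(self) -> None:
        self.clade = frozenset(self.clade)
        if len(self.clade) < 2:
            raise ValueError("calibrated clade needs >= 2 tips")
        if self.sd <= 0:
            raise ValueError("calibration sd must be > 0")


class PartitionedAlignment:
    """Aligned matrix over a shared taxon set with named column partitions.

    Bases are coded 0..3 (A,C,G,T); 4 means missing (N or gap). Partitions
    are disjoint column-index arrays covering all columns.
    """

    def __init__(self, taxa: list[str], matrix: np.ndarray, partitions: list[Partition]):
        self.taxa = list(taxa)
        self.matrix = matrix
        self.partitions = partitions
        cover = np.concatenate([p.columns for p in partitions]) if partitions else np.array([])
        if len(cover) != matrix.shape[1] or len(np.unique(cover)) != len(cover):
            raise ValueError("partitions must disjointly cover all columns")
        self._patterns: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def empirical_freqs(self, partition: Partition) -> tuple[float, ...]:
        sub = self.matrix[:, partition.columns]
        counts = np.bincount(sub[sub < 4], minlength=4).astype(float)
        if counts.sum() == 0:
            return (0.25, 0.25, 0.25, 0.25)
        counts = np.maximum(counts, 1.0)  # guard empty states
        f = counts / counts.sum()
        return tuple(f)

    def patterns(self, partition: Partition) -> tuple[np.ndarray, np.ndarray]:
        """Site-pattern compression of one partition: (codes (ntaxa, npat),
        counts (npat,))."""
        if partition.name not in self._patterns:
            sub = self.matrix[:, partition.columns]
            uniq, counts = np.unique(sub, axis=1, return_counts=True)
            self._patterns[partition.name] = (uniq, counts.astype(float))
        return self._patterns[partition.name]


def sequences_to_matrix(taxa: list[str], seqs: dict[str, str], n_columns: int) -> np.ndarray:
    mat = np.full((len(taxa), n_columns), 4, dtype=np.int8)
    for i, taxon in enumerate(taxa):
        if taxon in seqs:
            codes = encode(seqs[taxon])
            codes = np.where(codes > 4, 4, codes)  # gaps -> missing
            mat[i] = codes
    return mat


def concatenate(
    partition_alignments: list[tuple[str, list[NucleotideSequence]]],
    codon_split: tuple[str, ...] = (),
    default_model: SubstitutionModelParams | None = None,
) -> PartitionedAlignment:
    """Concatenate named gene alignments into one partitioned matrix.

    Taxa missing from a gene get an all-missing block. Genes named in
    codon_split contribute their columns, in each gene's own reading frame,
    to three pooled codon-position partitions instead of a gene partition.
    """
    default_model = default_model or SubstitutionModelParams(
        gamma_shape=0.5, n_gamma_categories=4, p_inv=0.1
    )
    taxa: list[str] = []
    for _, seqs in partition_alignments:
        ids = [s.id for s in seqs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate taxon within a partition")
        for t in ids:
            if t not in taxa:
                taxa.append(t)
    blocks: dict[str, str] = {}
    gene_cols: dict[str, np.ndarray] = {}
    offset = 0
    all_seqs: dict[str, list[str]] = {t: [] for t in taxa}
    for name, seqs in partition_alignments:
        lengths = {len(s.bases) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"partition {name!r}: unequal sequence lengths")
        L = lengths.pop()
        by_id = {s.id: s.bases for s in seqs}
        for t in taxa:
            all_seqs[t].append(by_id.get(t, "N" * L))
        gene_cols[name] = np.arange(offset, offset + L)
        offset += L
    matrix = sequences_to_matrix(taxa, {t: "".join(parts) for t, parts in all_seqs.items()}, offset)
    partitions: list[Partition] = []
    codon_pools: list[list[np.ndarray]] = [[], [], []]
    for name, _ in partition_alignments:
        cols = gene_cols[name]
        if name in codon_split:
            for pos in range(3):
                codon_pools[pos].append(cols[pos::3])
        else:
            partitions.append(Partition(name, cols, replace(default_model)))
    for pos in range(3):
        if codon_pools[pos]:
            cols = np.concatenate(codon_pools[pos])
            partitions.append(Partition(f"codon{pos + 1}", cols, replace(default_model)))
    aln = PartitionedAlignment(taxa, matrix, partitions)
    for p in aln.partitions:
        p.model = replace(p.model, base_freqs=aln.empirical_freqs(p))
    return aln


# ---------------------------------------------------------------------------
# Likelihood


_EYE5 = np.vstack([np.eye(4), np.ones(4)])


def _pruning_loglik(
    tip_partials: np.ndarray,
    counts: np.ndarray,
    gtr: GtrModel,
    chrono: Chronogram,
    edge_subs: np.ndarray,
) -> float:
    """Felsenstein pruning over compressed site patterns for one partition.

    tip_partials has shape (n_tips, npat, 4); missing data contributes
    partial likelihood 1 in every state. Per-node rescaling keeps partials
    in range.
    """
    npat = tip_partials.shape[1]
    n_tips = chrono.n_tips
    log_scale = np.zeros(npat)
    # all edge transition matrices in one shot, transposed for right-matmul
    Pt_all = gtr.transition_matrices_batch(edge_subs).transpose(0, 1, 3, 2)
    partial: dict[int, np.ndarray] = {}  # (ncat, npat, 4) per internal node
    for node in chrono.postorder:
        msg = None
        for child in chrono.children[node]:
            # message_i = sum_j P_ij * partial_j, batched over categories
            if child < n_tips:
                term = np.matmul(tip_partials[child][None, :, :], Pt_all[child])
            else:
                term = np.matmul(partial.pop(child), Pt_all[child])
            msg = term if msg is None else msg * term
        scale = msg.max(axis=(0, 2))
        scale = np.where(scale > 0, scale, 1.0)
        log_scale += np.log(scale)
        partial[node] = msg / scale[None, :, None]
    root_partial = partial[chrono.root]  # (ncat, npat, 4)
    per_cat = root_partial @ gtr.pi  # (ncat, npat)
    lik = gtr.weights @ per_cat
    if (lik <= 0).any():
        raise ValueError("non-finite partition likelihood")
    total = float(counts @ (np.log(lik) + log_scale))
    if not math.isfinite(total):
        raise ValueError("non-finite partition likelihood")
    return total


def _partition_loglik(
    codes: np.ndarray,
    counts: np.ndarray,
    gtr: GtrModel,
    chrono: Chronogram,
    edge_subs: np.ndarray,
) -> float:
    return _pruning_loglik(_EYE5[codes], counts, gtr, chrono, edge_subs)


class _LikelihoodEngine:
    """Caches pattern-compressed tip partials in chronogram tip order so the
    MCMC inner loop evaluates the likelihood without re-indexing."""

    def __init__(self, aln: PartitionedAlignment, chrono: Chronogram):
        if set(aln.taxa) != set(chrono.tip_labels):
            raise ValueError("alignment and tree taxa differ")
        order = [aln.taxa.index(lab) for lab in chrono.tip_labels]
        self.chrono = chrono
        self.parts = []
        for p in aln.partitions:
            codes, counts = aln.patterns(p)
            self.parts.append((p.name, _EYE5[codes[order]], counts))

    def loglik(self, edge_subs: np.ndarray, models: dict[str, GtrModel]) -> float:
        total = 0.0
        for name, tips, counts in self.parts:
            total += _pruning_loglik(tips, counts, models[name], self.chrono, edge_subs)
        return total


def log_likelihood(
    aln: PartitionedAlignment,
    chrono: Chronogram,
    branch_rates: np.ndarray | None = None,
    clock_rate: float = 1.0,
    models: dict[str, GtrModel] | None = None,
) -> float:
    """Total log-likelihood over partitions.

    Branch length for the likelihood is duration (Myr) x branch-rate
    multiplier x clock_rate (subs/site/Myr).
    """
    if set(aln.taxa) != set(chrono.tip_labels):
        raise ValueError("alignment and tree taxa differ")
    if branch_rates is None:
        branch_rates = np.ones(chrono.n_nodes)
    durations = chrono.durations()
    edge_subs = durations * branch_rates * clock_rate
    # pruning indexes tips by chronogram tip order
    order = [aln.taxa.index(lab) for lab in chrono.tip_labels]
    total = 0.0
    for p in aln.partitions:
        codes, counts = aln.patterns(p)
        codes = codes[order]
        gtr = models[p.name] if models else GtrModel(p.model)
        total += _partition_loglik(codes, counts, gtr, chrono, edge_subs)
    return total


# ---------------------------------------------------------------------------
# Priors


def _lognormal_logpdf(x: float, mu: float, sigma: float) -> float:
    if x <= 0:
        return -np.inf
    z = (math.log(x) - mu) / sigma
    return -math.log(x * sigma * math.sqrt(2 * math.pi)) - 0.5 * z * z


def _normal_logpdf(x: float, mu: float, sigma: float) -> float:
    z = (x - mu) / sigma
    return -math.log(sigma * math.sqrt(2 * math.pi)) - 0.5 * z * z


def yule_log_density(chrono: Chronogram, birth_rate: float) -> float:
    """Declared Yule normalisation: sum over internal nodes of
    log(lambda) - lambda * age. For two tips this is the exponential root-age
    density lambda * exp(-lambda * t)."""
    if birth_rate <= 0:
        return -np.inf
    ages = chrono.ages[chrono.postorder]
    return float(len(ages) * math.log(birth_rate) - birth_rate * ages.sum())


def log_prior(
    chrono: Chronogram,
    calibrations: list[Calibration],
    yule_birth_rate: float,
    clock_sd: float,
    branch_rates: np.ndarray | None = None,
    clock_rate: float | None = None,
    models: list[SubstitutionModelParams] | None = None,
    mrca_cache: dict[frozenset, int] | None = None,
) -> float:
    """Joint log prior of the dating model at the current state."""
    if clock_sd <= 0:
        return -np.inf
    lp = yule_log_density(chrono, yule_birth_rate)
    for cal in calibrations:
        node = mrca_cache[cal.clade] if mrca_cache else chrono.mrca(cal.clade)
        if mrca_cache is None and not chrono.is_monophyletic(cal.clade):
            raise ValueError(f"calibrated clade {sorted(cal.clade)} is not monophyletic")
        lp += _normal_logpdf(chrono.ages[node], cal.mean_age, cal.sd)
    if branch_rates is not None:
        mu = -0.5 * clock_sd**2  # real-space mean 1
        for i in range(chrono.n_nodes):
            if chrono.parent[i] >= 0:
                lp += _lognormal_logpdf(branch_rates[i], mu, clock_sd)
    # hyperpriors
    lp += _lognormal_logpdf(yule_birth_rate, 0.0, 2.0)
    lp += -clock_sd  # Exponential(1), log density up to constant
    if clock_rate is not None:
        lp += _lognormal_logpdf(clock_rate, -3.0, 3.0)
    if models:
        for m in models:
            for x in m.exchangeabilities:
                lp += _lognormal_logpdf(x, 0.0, 1.5)
            if m.gamma_shape is not None:
                lp += -m.gamma_shape  # Exponential(1)
            if not (0 <= m.p_inv < 1):
                return -np.inf
    return float(lp)


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class McmcOptions:
    sample_model_params: bool = True
    sample_clock_rate: bool = True
    age_window_frac: float = 1.0  # slide window as fraction of the free interval
    scale_factor: float = 0.3  # multiplier half-width on log scale


def _repair_initial_ages(
    chrono: Chronogram, calibrations: list[Calibration], mrca: dict[frozenset, int]
) -> None:
    """Pin calibrated nodes at their prior means, scale uncalibrated
    descendants below them, then push uncalibrated parents above their
    children. Two pinned nodes in ancestor order conflict is unrecoverable."""
    pinned = {}
    for cal in calibrations:
        node = mrca[cal.clade]
        chrono.ages[node] = cal.mean_age
        pinned[node] = cal.mean_age
    # downward: pull provisional ages under their (possibly pinned) parents
    for node in reversed(chrono.postorder):
        for child in chrono.children[node]:
            if child >= chrono.n_tips and child not in pinned:
                if chrono.ages[child] >= chrono.ages[node]:
                    chrono.ages[child] = 0.9 * chrono.ages[node]
    # upward: restore parent > child where the downward pass could not
    for node in chrono.postorder:
        lo = max(chrono.ages[c] for c in chrono.children[node])
        if chrono.ages[node] <= lo:
            if node in pinned:
                raise ValueError(
                    f"calibration at node {node} ({pinned[node]} Myr) conflicts with "
                    f"a descendant age {lo}"
                )
            chrono.ages[node] = lo * 1.05 + 0.1


def run_mcmc(
    aln: PartitionedAlignment,
    topology: Chronogram,
    calibrations: list[Calibration],
    n_generations: int = 500_000,
    sample_every: int = 100,
    seed: int = 0,
    options: McmcOptions | None = None,
) -> pd.DataFrame:
    """Metropolis-Hastings sampler over node ages, branch rates, model
    parameters and hyperparameters on a fixed topology.

    One random single-parameter proposal per generation. The returned trace
    has one row per sampled generation with posterior/likelihood/prior
    columns, per-internal-node ages (columns ``age_<node>``), and a boolean
    ``burn_in`` flag over the first 10% of generations.
    """
    options = options or McmcOptions()
    rng = np.random.default_rng(seed)
    chrono = topology.copy()
    mrca = {cal.clade: chrono.mrca(cal.clade) for cal in calibrations}
    for cal in calibrations:
        if not chrono.is_monophyletic(cal.clade):
            raise ValueError(f"calibrated clade {sorted(cal.clade)} is not monophyletic")
    _repair_initial_ages(chrono, calibrations, mrca)

    n_nodes = chrono.n_nodes
    has_parent = [i for i in range(n_nodes) if chrono.parent[i] >= 0]
    free_internal = list(chrono.postorder)
    branch_rates = np.ones(n_nodes)
    clock_sd = 0.1
    birth_rate = 0.2
    # substitution-model parameters are MCMC state: keep local copies so
    # the input alignment is never mutated
    part_names = [p.name for p in aln.partitions]
    part_params = {p.name: p.model for p in aln.partitions}
    models = {name: GtrModel(part_params[name]) for name in part_names}

    # crude data-informed clock-rate initialisation: mean p-distance over
    # non-missing pairs divided by twice the root age
    clock_rate = 1.0
    if options.sample_clock_rate:
        mat = aln.matrix
        dists = []
        for i in range(min(aln.n_taxa, 6)):
            for j in range(i + 1, min(aln.n_taxa, 6)):
                ok = (mat[i] < 4) & (mat[j] < 4)
                if ok.sum() > 50:
                    dists.append((mat[i][ok] != mat[j][ok]).mean())
        root_age = chrono.ages[chrono.root]
        clock_rate = max(float(np.mean(dists)) / (2 * root_age), 1e-4) if dists else 0.01

    engine = _LikelihoodEngine(aln, chrono)

    def model_param_list():
        return [part_params[name] for name in part_names]

    def loglik():
        edge_subs = chrono.durations() * branch_rates * clock_rate
        return engine.loglik(edge_subs, models)

    def logprior():
        return log_prior(
            chrono, calibrations, birth_rate, clock_sd, branch_rates, clock_rate,
            model_param_list(), mrca_cache=mrca,
        )

    cur_ll = loglik()
    cur_lp = logprior()

    moves = ["age"] * 2 + ["age_local"] * 6 + ["root"] * 2 + ["rate"] * 6 + ["sd"] * 2 + ["birth"]
    if options.sample_clock_rate:
        moves += ["clock"] * 3
    if options.sample_model_params:
        moves += ["exch", "shape", "pinv"]

    records = []
    burn_gen = int(0.1 * n_generations)

    for gen in range(n_generations + 1):
        move = moves[rng.integers(len(moves))]
        log_hastings = 0.0
        new_ll_needed = True
        undo = None
        invalid = False  # auto-reject without evaluating

        if move == "age" and len(free_internal) > 1:
            node = free_internal[rng.integers(len(free_internal) - 1)]  # excl. root
            lo = max(chrono.ages[c] for c in chrono.children[node])
            hi = chrono.ages[chrono.parent[node]]
            old = chrono.ages[node]
            chrono.ages[node] = rng.uniform(lo, hi)
            undo = ("age", node, old)
        elif move == "age_local" and len(free_internal) > 1:
            node = free_internal[rng.integers(len(free_internal) - 1)]
            lo = max(chrono.ages[c] for c in chrono.children[node])
            hi = chrono.ages[chrono.parent[node]]
            old = chrono.ages[node]
            delta = 0.02 * chrono.ages[chrono.root]
            new = old + rng.uniform(-delta, delta)
            if not (lo < new < hi):
                invalid = True
            else:
                chrono.ages[node] = new
            undo = ("age", node, old)
        elif move in ("age", "age_local", "root"):
            node = chrono.root
            m = math.exp(options.scale_factor * (rng.random() - 0.5))
            old = chrono.ages[node]
            new = old * m
            if new <= max(chrono.ages[c] for c in chrono.children[node]):
                invalid = True
            else:
                chrono.ages[node] = new
                log_hastings = math.log(m)
            undo = ("age", node, old)
        elif move == "rate":
            edge = has_parent[rng.integers(len(has_parent))]
            m = math.exp(options.scale_factor * (rng.random() - 0.5))
            old = branch_rates[edge]
            branch_rates[edge] = old * m
            log_hastings = math.log(m)
            undo = ("rate", edge, old)
        elif move == "clock":
            m = math.exp(options.scale_factor * (rng.random() - 0.5))
            old = clock_rate
            clock_rate = old * m
            log_hastings = math.log(m)
            undo = ("clock", None, old)
        elif move == "sd":
            m = math.exp(options.scale_factor * (rng.random() - 0.5))
            old = clock_sd
            clock_sd = old * m
            log_hastings = math.log(m)
            undo = ("sd", None, old)
            new_ll_needed = False
        elif move == "birth":
            m = math.exp(options.scale_factor * (rng.random() - 0.5))
            old = birth_rate
            birth_rate = old * m
            log_hastings = math.log(m)
            undo = ("birth", None, old)
            new_ll_needed = False
        elif move == "exch":
            name = part_names[rng.integers(len(part_names))]
            i = rng.integers(6)
            m = math.exp(options.scale_factor * (rng.random() - 0.5))
            old_model = part_params[name]
            ex = list(old_model.exchangeabilities)
            ex[i] *= m
            part_params[name] = replace(old_model, exchangeabilities=tuple(ex))
            models[name] = GtrModel(part_params[name])
            log_hastings = math.log(m)
            undo = ("model", name, old_model)
        elif move == "shape":
            name = part_names[rng.integers(len(part_names))]
            old_model = part_params[name]
            if old_model.gamma_shape is None:
                invalid = True
            else:
                m = math.exp(options.scale_factor * (rng.random() - 0.5))
                part_params[name] = replace(old_model, gamma_shape=old_model.gamma_shape * m)
                models[name] = GtrModel(part_params[name])
                log_hastings = math.log(m)
            undo = ("model", name, old_model)
        elif move == "pinv":
            name = part_names[rng.integers(len(part_names))]
            old_model = part_params[name]
            new_pinv = old_model.p_inv + rng.uniform(-0.05, 0.05)
            if not (0 <= new_pinv < 0.99):
                invalid = True
            else:
                part_params[name] = replace(old_model, p_inv=new_pinv)
                models[name] = GtrModel(part_params[name])
            undo = ("model", name, old_model)
        else:
            invalid = True
            undo = ("noop", None, None)

        if invalid:
            new_ll = cur_ll
            accept = False
        elif math.isinf(new_lp := logprior()) and new_lp < 0:
            new_ll = cur_ll
            accept = False
        else:
            new_ll = loglik() if new_ll_needed else cur_ll
            log_ratio = (new_ll + new_lp) - (cur_ll + cur_lp) + log_hastings
            accept = log_ratio >= 0 or rng.random() < math.exp(log_ratio)
        if accept:
            cur_ll, cur_lp = new_ll, new_lp
        else:
            kind, key, old = undo
            if kind == "age":
                chrono.ages[key] = old
            elif kind == "rate":
                branch_rates[key] = old
            elif kind == "clock":
                clock_rate = old
            elif kind == "sd":
                clock_sd = old
            elif kind == "birth":
                birth_rate = old
            elif kind == "model":
                part_params[key] = old
                models[key] = GtrModel(old)

        if gen % sample_every == 0:
            rec = {
                "gen": gen,
                "posterior": cur_ll + cur_lp,
                "loglik": cur_ll,
                "logprior": cur_lp,
                "birth_rate": birth_rate,
                "clock_sd": clock_sd,
                "clock_rate": clock_rate,
                "mean_branch_rate": float(branch_rates[has_parent].mean()),
                "burn_in": gen < burn_gen,
            }
            for node in chrono.postorder:
                rec[f"age_{node}"] = chrono.ages[node]
            records.append(rec)

    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Trace summaries


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    m = max(int(math.ceil(mass * n)), 1)
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS = n / (1 + 2 sum rho_k), autocorrelations truncated at the first
    non-positive value. A constant trace has ESS n by convention."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 2 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1 + 2 * s))


def summarize_trace(trace: pd.DataFrame, burn_in_frac: float = 0.10) -> pd.DataFrame:
    """Posterior mean, 95% HPD and ESS per numeric trace column."""
    cut = int(burn_in_frac * len(trace))
    post = trace.iloc[cut:]
    if len(post) < 10:
        raise ValueError("fewer than 10 post-burn-in samples")
    rows = []
    for col in post.columns:
        if col in ("gen", "burn_in") or not np.issubdtype(post[col].dtype, np.number):
            continue
        vals = post[col].to_numpy(dtype=float)
        lo, hi = hpd_interval(vals)
        rows.append(
            {
                "parameter": col,
                "mean": float(vals.mean()),
                "hpd95_low": lo,
                "hpd95_high": hi,
                "ess": effective_sample_size(vals),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
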