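"""Likelihood, priors, MCMC machinery and trace summaries."""

import itertools
import math

import numpy as np
import pytest

from museomics.dating import (
    Calibration,
    Partition,
    PartitionedAlignment,
    concatenate,
    effective_sample_size,
    hpd_interval,
    log_likelihood,
    log_prior,
    run_mcmc,
    sequences_to_matrix,
    summarize_trace,
    yule_log_density,
)
from museomics.io import NucleotideSequence
from museomics.simulate import evolve_on_tree, simulate_reference
from museomics.substmodel import JC, GtrModel, SubstitutionModelParams
from museomics.trees import Chronogram, random_chronogram


def make_alignment(labels, seqs, model=None):
    n_cols = len(next(iter(seqs.values())))
    mat = sequences_to_matrix(labels, seqs, n_cols)
    model = model or JC
    part = Partition("all", np.arange(n_cols), model)
    return PartitionedAlignment(labels, mat, [part])


def two_tip_chrono(t):
    return Chronogram(
        ["A", "B"], {2: (0, 1)}, np.array([2, 2, -1]), np.array([0.0, 0.0, t]), [2]
    )


# ---------------------------------------------------------------------------
# concatenate


def test_concatenate_partition_layout():
    def gene(name, taxa, length, seed):
        ref = simulate_reference(length, 0.5, seed)
        return (name, [NucleotideSequence(t, ref.bases) for t in taxa])

    taxa = ["a", "b", "c"]
    named = [
        gene("12S", taxa, 512, 1),
        gene("16S", taxa, 483, 2),
        gene("cytb", taxa, 657, 3),
        gene("ND4", taxa, 659, 4),
    ]
    aln = concatenate(named, codon_split=("cytb", "ND4"))
    assert aln.n_columns == 2311
    assert len(aln.partitions) == 5  # 12S, 16S, three pooled codon positions
    cover = np.sort(np.concatenate([p.columns for p in aln.partitions]))
    assert (cover == np.arange(2311)).all()


def test_concatenate_missing_taxon_block_is_all_missing():
    g1 = ("g1", [NucleotideSequence("a", "ACGT"), NucleotideSequence("b", "ACGT")])
    g2 = ("g2", [NucleotideSequence("a", "GGCC")])
    aln = concatenate([g1, g2])
    b = aln.taxa.index("b")
    assert (aln.matrix[b, 4:] == 4).all()
    assert (aln.matrix[b, :4] != 4).all()


def test_concatenate_single_partition_identity():
    g1 = ("g1", [NucleotideSequence("a", "ACGT")])
    aln = concatenate([g1])
    assert aln.n_columns == 4 and len(aln.partitions) == 1


def test_concatenate_duplicate_taxon_errors():
    g1 = ("g1", [NucleotideSequence("a", "ACGT"), NucleotideSequence("a", "ACGT")])
    with pytest.raises(ValueError, match="duplicate"):
        concatenate([g1])


# ---------------------------------------------------------------------------
# likelihood


def test_identical_sequences_zero_tree():
    aln = make_alignment(["A", "B"], {"A": "ACGTAC", "B": "ACGTAC"})
    chrono = two_tip_chrono(1e-12)
    ll = log_likelihood(aln, chrono, clock_rate=0.0)
    assert ll == pytest.approx(6 * math.log(0.25), abs=1e-6)


def test_jc_two_taxa_closed_form():
    t = 0.2  # per-branch substitutions
    chrono = two_tip_chrono(t)
    match = math.log(1 / 4) + math.log(1 / 4 + 3 / 4 * math.exp(-8 * t / 3))
    mismatch = math.log(1 / 4) + math.log(1 / 4 - 1 / 4 * math.exp(-8 * t / 3))
    aln_same = make_alignment(["A", "B"], {"A": "A", "B": "A"})
    aln_diff = make_alignment(["A", "B"], {"A": "A", "B": "C"})
    assert log_likelihood(aln_same, chrono, clock_rate=1.0) == pytest.approx(match, abs=1e-9)
    assert log_likelihood(aln_diff, chrono, clock_rate=1.0) == pytest.approx(mismatch, abs=1e-9)


def test_missing_data_gives_zero_loglik():
    aln = make_alignment(["A", "B"], {"A": "NNN", "B": "NNN"})
    chrono = two_tip_chrono(0.5)
    assert log_likelihood(aln, chrono, clock_rate=1.0) == pytest.approx(0.0, abs=1e-9)


def test_root_reposition_invariance():
    """Reversibility: only the sum of path lengths matters (pulley principle)."""
    model = SubstitutionModelParams(
        exchangeabilities=(1.2, 3.1, 0.7, 0.9, 4.0, 1.0),
        base_freqs=(0.3, 0.2, 0.2, 0.3),
        gamma_shape=0.7,
    )
    aln = make_alignment(["A", "B"], {"A": "ACGGTTAC", "B": "ATGGCTAA"}, model)
    chrono = two_tip_chrono(0.3)
    ll_mid = log_likelihood(aln, chrono, clock_rate=1.0)
    rates = np.array([1.6, 0.4, 1.0])  # same total path 0.3*1.6 + 0.3*0.4 = 0.6
    ll_skew = log_likelihood(aln, chrono, branch_rates=rates, clock_rate=1.0)
    assert ll_mid == pytest.approx(ll_skew, abs=1e-9)


def enumerate_topologies(tips):
    """All rooted binary topologies over a label list, as nested tuples."""
    if len(tips) == 1:
        yield tips[0]
        return
    first, rest = tips[0], tips[1:]
    for k in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, k):
            left = [first, *left_rest]
            right = [t for t in rest if t not in left_rest]
            if not right:
                continue
            for lt in enumerate_topologies(left):
                for rt in enumerate_topologies(right):
                    yield (lt, rt)


def chronogram_from_nested(nested, labels, rng):
    """Random valid ages on a nested-tuple topology."""
    n = len(labels)
    children = {}
    ages = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=int)
    postorder = []
    counter = [n]

    def build(node):
        if isinstance(node, str):
            return labels.index(node)
        l = build(node[0])
        r = build(node[1])
        idx = counter[0]
        counter[0] += 1
        children[idx] = (l, r)
        parent[l] = parent[r] = idx
        ages[idx] = max(ages[l], ages[r]) + rng.uniform(0.05, 0.5)
        postorder.append(idx)
        return idx

    build(nested)
    return Chronogram(labels, children, parent, ages, postorder)


def brute_force_loglik(aln, chrono, gtr, edge_subs):
    """Oracle: explicit summation over all internal-node state assignments
    and rate categories."""
    order = [aln.taxa.index(lab) for lab in chrono.tip_labels]
    mat = aln.matrix[order]
    n_tips = chrono.n_tips
    internals = chrono.postorder
    total = 0.0
    for col in range(mat.shape[1]):
        col_lik = 0.0
        for rate, weight in zip(gtr.rates, gtr.weights):
            P = {
                node: gtr.transition_matrix(edge_subs[node] * rate)
                for node in range(chrono.n_nodes)
                if chrono.parent[node] >= 0
            }
            s = 0.0
            for states in itertools.product(range(4), repeat=len(internals)):
                assign = dict(zip(internals, states))
                p = gtr.pi[assign[chrono.root]]
                for node in range(chrono.n_nodes):
                    par = chrono.parent[node]
                    if par < 0:
                        continue
                    if node < n_tips:
                        obs = mat[node, col]
                        if obs == 4:
                            p *= 1.0  # marginalises to 1
                        else:
                            p *= P[node][assign[par], obs]
                    else:
                        p *= P[node][assign[par], assign[node]]
                s += p
            col_lik += weight * s
        total += math.log(col_lik)
    return total


def test_pruning_equals_bruteforce_small_trees(rng):
    """Spot check on 4-tip topologies with Γ+I and missing data; the full
    sweep over all topologies lives in the acceptance suite."""
    labels = ["t0", "t1", "t2", "t3"]
    model = SubstitutionModelParams(
        exchangeabilities=(1.5, 2.0, 0.8, 1.1, 3.0, 1.0),
        base_freqs=(0.28, 0.22, 0.24, 0.26),
        gamma_shape=0.6,
        p_inv=0.15,
    )
    gtr = GtrModel(model)
    seqs = {"t0": "ACN", "t1": "AGG", "t2": "CGT", "t3": "ANT"}
    aln = make_alignment(labels, seqs, model)
    for nested in itertools.islice(enumerate_topologies(labels), 5):
        chrono = chronogram_from_nested(nested, labels, rng)
        edge_subs = chrono.durations() * 0.8
        want = brute_force_loglik(aln, chrono, gtr, edge_subs)
        got = log_likelihood(aln, chrono, clock_rate=0.8, models={"all": gtr})
        assert got == pytest.approx(want, abs=1e-8)


# ---------------------------------------------------------------------------
# priors


def test_yule_two_tip_density():
    lam, t = 0.7, 3.0
    chrono = two_tip_chrono(t)
    assert yule_log_density(chrono, lam) == pytest.approx(math.log(lam) - lam * t)


def test_calibration_at_mode():
    chrono = two_tip_chrono(5.0)
    cal = Calibration(frozenset(["A", "B"]), 5.0, 0.01)
    lp_at = log_prior(chrono, [cal], 0.5, 0.1)
    chrono2 = two_tip_chrono(5.03)
    lp_off = log_prior(chrono2, [cal], 0.5, 0.1)
    # difference isolates the calibration + Yule terms; calibration dominates
    assert lp_at > lp_off
    # normal density at its mode, recovered by subtracting the other terms
    base = log_prior(chrono, [], 0.5, 0.1)
    assert lp_at - base == pytest.approx(-math.log(0.01 * math.sqrt(2 * math.pi)))


def test_relaxed_clock_term_peaks_at_unit_rates():
    chrono = two_tip_chrono(2.0)
    rates = np.ones(3)
    lps = [
        log_prior(chrono, [], 0.5, sd, branch_rates=rates) for sd in (0.5, 0.2, 0.05)
    ]
    assert lps[0] < lps[1] < lps[2]


def test_nonmonophyletic_calibration_errors(rng):
    chrono = random_chronogram(4, 1.0, rng)
    below = chrono.tips_below()
    # pick two tips that are not sisters under any cherry: take tips whose
    # mrca is the root but which do not form the full root clade
    labels = chrono.tip_labels
    for pair in itertools.combinations(labels, 2):
        node = chrono.mrca(pair)
        if below[node] != {labels.index(p) for p in pair}:
            with pytest.raises(ValueError, match="monophyletic"):
                log_prior(chrono, [Calibration(frozenset(pair), 1.0, 0.01)], 0.5, 0.1)
            break


# ---------------------------------------------------------------------------
# MCMC and summaries


def test_mcmc_deterministic(rng):
    chrono = random_chronogram(4, 0.5, rng)
    root = simulate_reference(200, 0.5, 40)
    seqs = evolve_on_tree(root, chrono, JC, seed=41, clock_rate=0.05)
    aln = make_alignment([s.id for s in seqs], {s.id: s.bases for s in seqs})
    cal = Calibration(frozenset(chrono.tip_labels), chrono.ages[chrono.root], 0.01)
    t1 = run_mcmc(aln, chrono, [cal], n_generations=2000, sample_every=100, seed=7)
    t2 = run_mcmc(aln, chrono, [cal], n_generations=2000, sample_every=100, seed=7)
    assert t1.equals(t2)


def test_hpd_normal_samples():
    x = np.random.default_rng(1).normal(0, 1, 100_000)
    lo, hi = hpd_interval(x)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hpd_constant_and_ess_constant():
    x = np.full(100, 3.3)
    lo, hi = hpd_interval(x)
    assert lo == hi == 3.3
    assert effective_sample_size(x) == 100


def test_ess_ar1():
    phi = 0.9
    rng_ = np.random.default_rng(2)
    n = 200_000
    x = np.empty(n)
    x[0] = 0
    eps = rng_.normal(size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    want = n * (1 - phi) / (1 + phi)
    got = effective_sample_size(x)
    assert abs(got - want) / want < 0.2


def test_summarize_trace_errors_when_short():
    import pandas as pd

    trace = pd.DataFrame({"gen": range(5), "x": range(5)})
    with pytest.raises(ValueError):
        summarize_trace(trace)
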