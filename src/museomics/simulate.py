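"""Synthetic data generation for every stage of the pipeline.

Four generators: (a) museum-style shotgun reads — short lognormal fragments,
optional terminal cytosine-deamination damage, a contaminant background
diluting the endogenous fraction; (b) clean amplicon reads tiling a
mitogenome at high depth; (c) alignments evolved on a dated tree under
GTR+Γ(+I); (d) two-population meristic morphology tables with group
mean/SD/range parameters taken from published scale-count summaries for the
two rinkhals populations.

Every generator is deterministic for a fixed seed. Read simulators emit a
truth table (source, true coordinates, strand) so downstream accuracy can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NucleotideSequence, Read, Region
from .mapping import revcomp
from .substmodel import GtrModel, SubstitutionModelParams
from .trees import Chronogram

_BASES = np.array(list("ACGT"))


@dataclass
class DamageModel:
    """Terminal deamination damage: C→T near the 5' end and G→A near the 3'
    end, with per-position probability delta * decay_lambda**offset.

    Disabled by default: UDG/EndoVIII treatment during library preparation
    excises uracils, so damage-free reads are the expected study condition;
    enabling damage lets robustness be probed.
    """

    delta5: float = 0.0
    delta3: float = 0.0
    decay_lambda: float = 0.5
    enabled: bool = False

    def __post_init__(self) -> None:
        for p in (self.delta5, self.delta3):
            if not (0 <= p <= 1):
                raise ValueError("damage probabilities must be in [0, 1]")
        if not (0 < self.decay_lambda <= 1):
            raise ValueError("decay_lambda must be in (0, 1]")


@dataclass
class ReadSimConfig:
    """Shotgun read-simulation settings.

    Defaults mirror a museum-genomics shotgun library: 75 bp single-end
    reads, short lognormal fragments, low sequencing error. The endogenous
    fraction dilutes target reads with reads drawn from a contaminant genome.
    """

    coverage: float = 25.0
    frag_len_mean: float = 60.0
    frag_len_sd: float = 20.0
    endogenous_fraction: float = 1.0
    contaminant_ref: NucleotideSequence | None = None
    seq_error: float = 0.001
    read_len: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not (0 <= self.endogenous_fraction <= 1):
            raise ValueError("endogenous_fraction must be in [0, 1]")
        if self.endogenous_fraction < 1 and self.contaminant_ref is None:
            raise ValueError("contaminant_ref required when endogenous_fraction < 1")


def simulate_reference(length: int, gc: float = 0.5, seed: int = 0) -> NucleotideSequence:
    """Random reference sequence with expected GC fraction ``gc``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(_BASES, size=length, p=p)
    return NucleotideSequence("simref", "".join(bases))


def _fragment_lengths(n: int, cfg: ReadSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Lognormal fragment lengths (real-space mean/sd per cfg), truncated to
    [20, 2*read_len] by resampling-free clipping."""
    m, s = cfg.frag_len_mean, cfg.frag_len_sd
    sigma2 = np.log(1 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    lens = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.clip(np.round(lens), 20, 2 * cfg.read_len).astype(int)


def _apply_damage(bases: str, dmg: DamageModel, rng: np.random.Generator) -> str:
    if not dmg.enabled:
        return bases
    arr = list(bases)
    L = len(arr)
    for i in range(L):
        p5 = dmg.delta5 * dmg.decay_lambda**i
        p3 = dmg.delta3 * dmg.decay_lambda ** (L - 1 - i)
        if arr[i] == "C" and p5 > 0 and rng.random() < p5:
            arr[i] = "T"
        elif arr[i] == "G" and p3 > 0 and rng.random() < p3:
            arr[i] = "A"
    return "".join(arr)


def _apply_seq_error(bases: str, p: float, rng: np.random.Generator) -> str:
    if p <= 0:
        return bases
    arr = np.array(list(bases))
    hit = rng.random(len(arr)) < p
    for i in np.nonzero(hit)[0]:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[rng.integers(3)]
    return "".join(arr)


def _draw_reads_from(
    ref: NucleotideSequence,
    n: int,
    cfg: ReadSimConfig,
    dmg: DamageModel,
    rng: np.random.Generator,
    source: str,
    id_offset: int,
) -> tuple[list[Read], list[dict]]:
    reads: list[Read] = []
    truth: list[dict] = []
    L = len(ref.bases)
    frag_lens = _fragment_lengths(n, cfg, rng)
    starts = rng.integers(0, np.maximum(L - frag_lens + 1, 1))
    strands = rng.random(n) < 0.5
    for i in range(n):
        flen = min(int(frag_lens[i]), L)
        start = int(starts[i])
        frag = ref.bases[start : start + flen]
        strand = "+" if strands[i] else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_damage(frag, dmg, rng)
        seq = frag[: cfg.read_len]
        seq = _apply_seq_error(seq, cfg.seq_error, rng)
        rid = f"{source[:3]}_{id_offset + i}"
        reads.append(Read(rid, seq, [40] * len(seq)))
        truth.append(
            {
                "read_id": rid,
                "source": source,
                "ref_id": ref.id,
                "start": start,
                "end": start + flen,
                "strand": strand,
            }
        )
    return reads, truth


def simulate_reads(
    ref: NucleotideSequence, cfg: ReadSimConfig, dmg: DamageModel | None = None
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate a shotgun library with a contaminant background.

    The endogenous read count targets cfg.coverage * len(ref) sequenced
    bases; contaminant reads are added so endogenous reads make up
    cfg.endogenous_fraction of the library in expectation. Returns the reads
    (shuffled) and a truth table with true source and coordinates.
    """
    dmg = dmg or DamageModel()
    rng = np.random.default_rng(cfg.seed)
    mean_read = min(cfg.read_len, cfg.frag_len_mean)
    n_endog = int(round(cfg.coverage * len(ref.bases) / mean_read))
    if n_endog == 0:
        return [], pd.DataFrame(
            columns=["read_id", "source", "ref_id", "start", "end", "strand"]
        )
    reads, truth = _draw_reads_from(ref, n_endog, cfg, dmg, rng, "endogenous", 0)
    if cfg.endogenous_fraction < 1:
        f = cfg.endogenous_fraction
        n_cont = int(round(n_endog * (1 - f) / f))
        # contamination is modern DNA: no deamination damage
        c_reads, c_truth = _draw_reads_from(
            cfg.contaminant_ref, n_cont, cfg, DamageModel(), rng, "contaminant", n_endog
        )
        reads += c_reads
        truth += c_truth
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth_df = pd.DataFrame([truth[i] for i in order])
    return reads, truth_df


def simulate_amplicons(
    ref: NucleotideSequence,
    amplicon_coords: list[Region],
    depth: float,
    read_len: int = 75,
    seed: int = 0,
) -> list[Read]:
    """Error-free, undamaged reads uniformly tiling each amplicon at ~depth."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for region in amplicon_coords:
        if region.start < 0 or region.end > len(ref.bases):
            raise ValueError(f"amplicon {region} outside reference")
        span = len(region)
        rl = min(read_len, span)
        n = int(round(depth * span / rl))
        starts = rng.integers(region.start, max(region.end - rl, region.start) + 1, size=n)
        strands = rng.random(n) < 0.5
        for i, start in enumerate(starts):
            seq = ref.bases[start : start + rl]
            if strands[i]:
                seq = revcomp(seq)
            reads.append(
                Read(f"amp_{region.start}_{i}", seq, [40] * len(seq))
            )
    return reads


def evolve_on_tree(
    root_seq: NucleotideSequence,
    tree: Chronogram,
    model: SubstitutionModelParams,
    seed: int = 0,
    branch_rates: np.ndarray | None = None,
    clock_rate: float = 1.0,
) -> list[NucleotideSequence]:
    """Evolve an alignment on a dated tree under the GTR+Γ(+I) CTMC.

    Edge lengths in expected substitutions/site are duration * branch rate *
    clock_rate. Among-site rate categories (including the invariant class)
    are drawn once per site and shared across the whole tree. Returns aligned
    tip sequences, all the same length as root_seq, in tip order.
    """
    gtr = GtrModel(model)
    rng = np.random.default_rng(seed)
    L = len(root_seq.bases)
    from .mapping import encode

    root_codes = encode(root_seq.bases)
    if (root_codes > 3).any():
        raise ValueError("root sequence must be over {A,C,G,T}")
    site_cat = rng.choice(len(gtr.rates), size=L, p=gtr.weights)
    site_rates = gtr.rates[site_cat]
    durations = tree.durations()
    if branch_rates is None:
        branch_rates = np.ones(tree.n_nodes)
    seqs: dict[int, np.ndarray] = {tree.root: root_codes.astype(np.int64)}
    # preorder: reverse of (postorder + tips), root first
    order = [tree.root]
    for node in reversed(tree.postorder):
        l, r = tree.children[node]
        order += [l, r]
    for node in order:
        if node == tree.root:
            continue
        t = durations[node] * branch_rates[node] * clock_rate
        parent_codes = seqs[tree.parent[node]]
        child = parent_codes.copy()
        for ci in range(len(gtr.rates)):
            mask = site_cat == ci
            if not mask.any():
                continue
            rate = gtr.rates[ci]
            if rate == 0 or t == 0:
                continue
            P = gtr.transition_matrix(t * rate)
            cum = P.cumsum(axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_codes[mask]]
            child[np.nonzero(mask)[0]] = (u[:, None] > rows).sum(axis=1)
        seqs[node] = child
    out = []
    for i, label in enumerate(tree.tip_labels):
        out.append(NucleotideSequence(label, "".join(_BASES[seqs[i]])))
    return out


# ---------------------------------------------------------------------------
# Morphology


@dataclass
class CharacterParams:
    """Mean, SD and optional truncation range of one meristic character in
    one population x sex group."""

    mean: float
    sd: float
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


#: Published scale-count summaries for the two rinkhals populations
#: (South Africa vs Zimbabwe), per sex where a character is dimorphic.
#: Keys: (population, sex) -> {character: CharacterParams}. Characters
#: shared across sexes use the same parameters under both sexes.
DEFAULT_GROUP_PARAMS: dict[tuple[str, str], dict[str, CharacterParams]] = {
    ("SA", "F"): {
        "midbody_rows": CharacterParams(18.6, 0.72, (17, 19)),
        "nape_rows": CharacterParams(17.9, 0.99, (17, 19)),
        "subcaudals": CharacterParams(39.0, 2.6, (35, 40)),
        "ventrals": CharacterParams(141.0, 6.5, (129, 148)),
    },
    ("SA", "M"): {
        "midbody_rows": CharacterParams(18.6, 0.72, (17, 19)),
        "nape_rows": CharacterParams(17.9, 0.99, (17, 19)),
        "subcaudals": CharacterParams(40.9, 3.1, (35, 46)),
        "ventrals": CharacterParams(129.0, 6.9, (117, 138)),
    },
    ("ZW", "F"): {
        "midbody_rows": CharacterParams(17.8, 0.95, (17, 19)),
        "nape_rows": CharacterParams(17.0, 0.43, (16, 18)),
        "subcaudals": CharacterParams(33.8, 2.3, (30, 37)),
        "ventrals": CharacterParams(128.0, 1.6, (126, 130)),
    },
    ("ZW", "M"): {
        "midbody_rows": CharacterParams(17.8, 0.95, (17, 19)),
        "nape_rows": CharacterParams(17.0, 0.43, (16, 18)),
        "subcaudals": CharacterParams(36.3, 1.8, (34, 38)),
        "ventrals": CharacterParams(122.0, 1.7, (119, 124)),
    },
}

#: Body-size parameters (mm) used when simulating SVL/TL for the ANCOVA;
#: TL is generated as a sex-specific fraction of SVL plus noise.
DEFAULT_SIZE_PARAMS = {
    "svl_mean": 650.0,
    "svl_sd": 90.0,
    "tl_ratio": {"F": 0.19, "M": 0.21},
    "tl_noise_sd": 8.0,
}


def simulate_morphology(
    group_params: dict[tuple[str, str], dict[str, CharacterParams]] | None = None,
    n_per_group: int | dict[tuple[str, str], int] = 10,
    seed: int = 0,
    include_size: bool = True,
    size_params: dict | None = None,
) -> pd.DataFrame:
    """Simulate a two-population meristic morphology table.

    Counts are rounded normals truncated to the stated range where one is
    given. With include_size, SVL and TL columns are added (TL a sex-specific
    fraction of SVL with noise) to support the ANCOVA.
    """
    group_params = group_params or DEFAULT_GROUP_PARAMS
    size_params = size_params or DEFAULT_SIZE_PARAMS
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for (pop, sex), chars in group_params.items():
        n = n_per_group[(pop, sex)] if isinstance(n_per_group, dict) else n_per_group
        for _ in range(n):
            row = {"specimen_id": f"{pop}_{sex}_{idx}", "population": pop, "sex": sex}
            idx += 1
            for name, p in chars.items():
                val = round(rng.normal(p.mean, p.sd)) if p.sd > 0 else round(p.mean)
                if p.range is not None:
                    val = min(max(val, p.range[0]), p.range[1])
                row[name] = float(val)
            if include_size:
                svl = max(rng.normal(size_params["svl_mean"], size_params["svl_sd"]), 250.0)
                ratio = size_params["tl_ratio"].get(sex, 0.20)
                tl = max(svl * ratio + rng.normal(0, size_params["tl_noise_sd"]), 40.0)
                row["SVL"] = round(svl, 1)
                row["TL"] = round(tl, 1)
            rows.append(row)
    df = pd.DataFrame(rows)
    df["population"] = df["population"].astype("category")
    return df
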