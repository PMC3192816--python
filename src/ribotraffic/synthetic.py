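"""Generators for every fixture class the tests and demos need.

* designer mRNAs (uniform bulk with one distinct central codon),
* codon-count-balanced mixtures of mRNA species,
* random gene sets with tunable codon usage bias (for the QLI/CAI analysis),
* synthetic yeast-like ORF fixtures (packaged stand-ins with engineered
  supply/demand structure), and
* exactly solvable micro-instances whose stationary distribution is obtained
  by enumerating the CTMC state space and solving the linear system.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MRNASpecies, TranslationSystem
from .io import SENSE_CODONS, CodonMap, TRNASpeciesTable, load_packaged_codon_map, load_packaged_trna_table

__all__ = [
    "make_designer_mrna",
    "MixtureSpec",
    "make_mixture",
    "SyntheticGene",
    "make_random_gene_set",
    "make_oracle_instance",
    "OracleSolution",
    "enumerate_ctmc",
    "designer_preset",
    "packaged_orf_records",
    "make_cell_cycle_gene_sets",
]


# ---------------------------------------------------------------------------
# designer mRNA and mixtures


def make_designer_mrna(
    L: int, bulk_species: int = 1, center_species: int = 2, copy_number: int = 1, w: int | None = None
) -> MRNASpecies:
    """Uniform mRNA of length L whose central codon (position ceil(L/2)) is
    of a different species."""
    if w is not None and L < w:
        raise ValueError(f"L={L} shorter than ribosome width w={w}")
    codons = np.full(L, bulk_species, dtype=np.int64)
    codons[(L + 1) // 2 - 1] = center_species
    return MRNASpecies(f"designer_L{L}", codons, copy_number)


@dataclass(frozen=True)
class MixtureSpec:
    """mRNA species with target shares of the total codon budget."""

    mrnas: list
    shares: list
    n_codons_target: int

    def __post_init__(self):
        if abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValueError("shares must sum to 1")
        if len(self.mrnas) != len(self.shares):
            raise ValueError("one share per mRNA species")


def make_mixture(spec: MixtureSpec) -> list:
    """Copy numbers realising the requested codon-count shares.

    Copies are assigned by largest remainder on the codon counts; every
    species must end up with at least one copy.
    """
    Ls = np.array([m.length for m in spec.mrnas], dtype=float)
    shares = np.asarray(spec.shares, dtype=float)
    frac = shares * spec.n_codons_target / Ls
    base = np.floor(frac + 1e-9).astype(np.int64)
    # add copies by largest codon deficit while they improve the fit
    while True:
        deficit = shares * spec.n_codons_target - base * Ls
        j = int(np.argmax(deficit))
        if deficit[j] < Ls[j] / 2:
            break
        base[j] += 1
    if np.any(base == 0):
        bad = [spec.mrnas[i].name for i in np.flatnonzero(base == 0)]
        raise ValueError(
            f"species {bad} would get zero copies; increase n_codons_target "
            f"(needs at least ~{int(2 * Ls.max() / shares.min())} codons)"
        )
    out = [
        MRNASpecies(m.name, m.codons, int(c)) for m, c in zip(spec.mrnas, base)
    ]
    return out


# ---------------------------------------------------------------------------
# random gene sets


@dataclass(frozen=True)
class SyntheticGene:
    name: str
    codon_strings: tuple  # DNA codons, no stop
    ids: np.ndarray  # 1-based tRNA species ids
    bias: float

    def to_mrna(self, copy_number: int = 1) -> MRNASpecies:
        return MRNASpecies(self.name, self.ids, copy_number)


def _codon_probabilities(
    bias: float, table: TRNASpeciesTable, code: CodonMap, allowed=None
) -> tuple:
    """Codon sampling distribution interpolating (log-linearly) between
    uniform over the 61 sense codons (bias 0) and supply-proportional
    (bias 1, each species' supply split evenly over its codons)."""
    sigma = table.gene_copy_number / table.gene_copy_number.sum()
    codons = [c for c in SENSE_CODONS if allowed is None or c in allowed]
    n_per_species = np.zeros(table.n_species)
    for c in codons:
        n_per_species[code[c] - 1] += 1
    logp = []
    for c in codons:
        i = code[c] - 1
        p1 = sigma[i] / n_per_species[i]
        logp.append((1.0 - bias) * np.log(1.0 / len(codons)) + bias * np.log(p1))
    p = np.exp(np.array(logp))
    return codons, p / p.sum()


def make_random_gene_set(
    n_genes: int,
    length_range: tuple,
    usage_bias,
    seed: int,
    table: TRNASpeciesTable | None = None,
    code: CodonMap | None = None,
) -> list:
    """Seeded random gene set spanning a codon-usage-bias gradient.

    ``usage_bias`` is either a scalar applied to every gene or a sequence of
    per-gene biases in [0, 1].
    """
    table = table or load_packaged_trna_table()
    code = code or load_packaged_codon_map()
    rng = np.random.default_rng(seed)
    biases = (
        np.full(n_genes, float(usage_bias))
        if np.isscalar(usage_bias)
        else np.asarray(usage_bias, dtype=float)
    )
    if biases.size != n_genes:
        raise ValueError("one bias per gene")
    lo, hi = length_range
    genes = []
    for gidx in range(n_genes):
        L = int(rng.integers(lo, hi + 1))
        codons, p = _codon_probabilities(float(biases[gidx]), table, code)
        picks = rng.choice(len(codons), size=L, p=p)
        cstr = tuple(codons[j] for j in picks)
        ids = np.array([code[c] for c in cstr], dtype=np.int64)
        genes.append(SyntheticGene(f"gene{gidx:04d}_b{biases[gidx]:.2f}", cstr, ids, float(biases[gidx])))
    return genes


# ---------------------------------------------------------------------------
# exact CTMC oracle


@dataclass
class OracleSolution:
    states: list  # state keys: (lattices tuple-of-tuples, charged tuple)
    pi: np.ndarray
    index: dict  # state key -> row
    J: np.ndarray  # per mRNA species
    rho: dict  # mRNA name -> exact reader-density profile
    c: np.ndarray  # exact charging level per tRNA species

    def state_probability(self, key) -> float:
        return float(self.pi[self.index[key]]) if key in self.index else 0.0


def state_key(positions, a) -> tuple:
    return (tuple(tuple(p) for p in positions), tuple(int(x) for x in a))


def _oracle_transitions(system: TranslationSystem, key):
    """Enumerate (rate, next_key) pairs; written directly from the model
    rules, used only via state-space enumeration + linear solve."""
    lats, a = key
    lat_species = []
    for r, m in enumerate(system.mrnas):
        lat_species.extend([r] * m.copy_number)
    inf = system.infinite_recharge
    for l, r in enumerate(lat_species):
        m = system.mrnas[r]
        ps = lats[l]
        if (not ps or ps[-1] > system.w) and system.alpha > 0:
            new = list(ps) + [1]
            nl = list(lats)
            nl[l] = tuple(new)
            yield system.alpha, (tuple(nl), a)
        for k, p in enumerate(ps):
            s = int(m.codons[p - 1]) - 1
            if p == m.length:
                ok = inf or not system.termination_consumes_trna or a[s] >= 1
                if ok:
                    nl = list(lats)
                    nl[l] = tuple(list(ps[:k]) + list(ps[k + 1 :]))
                    na = a
                    if system.termination_consumes_trna and not inf:
                        na = tuple(x - 1 if i == s else x for i, x in enumerate(a))
                    yield system.beta, (tuple(nl), na)
            else:
                clear = k == 0 or ps[k - 1] >= p + 1 + system.w
                avail = int(system.T[s]) if inf else a[s]
                if clear and avail >= 1:
                    nl = list(lats)
                    nl[l] = tuple(list(ps[:k]) + [p + 1] + list(ps[k + 1 :]))
                    na = a if inf else tuple(x - 1 if i == s else x for i, x in enumerate(a))
                    yield system.kappa * avail, (tuple(nl), na)
    if not inf:
        for i in range(system.n_species):
            bi = int(system.T[i]) - a[i]
            if bi > 0:
                na = tuple(x + 1 if i == j else x for j, x in enumerate(a))
                yield system.V[i] * bi / (system.K[i] + bi), (lats, na)


def enumerate_ctmc(system: TranslationSystem, max_states: int = 200_000) -> OracleSolution:
    """Breadth-first enumeration of the reachable state space from the
    empty/fully-charged initial condition, followed by a direct solve of
    the stationary linear system pi Q = 0."""
    init = state_key([[] for _ in range(system.n_lattices)], system.T)
    index = {init: 0}
    states = [init]
    edges = []
    frontier = [init]
    while frontier:
        nxt = []
        for key in frontier:
            for rate, dest in _oracle_transitions(system, key):
                if dest not in index:
                    if len(states) >= max_states:
                        raise ValueError("state space exceeds the oracle limit")
                    index[dest] = len(states)
                    states.append(dest)
                    nxt.append(dest)
                edges.append((index[key], index[dest], rate))
        frontier = nxt
    n = len(states)
    Q = np.zeros((n, n))
    for i, j, rate in edges:
        Q[i, j] += rate
        Q[i, i] -= rate
    A = Q.T.copy()
    A[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    pi = np.linalg.solve(A, rhs)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    lat_species = []
    for r, m in enumerate(system.mrnas):
        lat_species.extend([r] * m.copy_number)
    nspec = len(system.mrnas)
    J = np.zeros(nspec)
    rho = {m.name: np.zeros(m.length) for m in system.mrnas}
    c = np.zeros(system.n_species)
    for key, p_s in zip(states, pi):
        lats, a = key
        for i in range(system.n_species):
            ai = int(system.T[i]) if system.infinite_recharge else a[i]
            c[i] += p_s * ai / max(int(system.T[i]), 1)
        for l, r in enumerate(lat_species):
            m = system.mrnas[r]
            for pcs in lats[l]:
                rho[m.name][pcs - 1] += p_s / m.copy_number
            if lats[l] and lats[l][0] == m.length:
                s = int(m.codons[-1]) - 1
                ok = (
                    system.infinite_recharge
                    or not system.termination_consumes_trna
                    or a[s] >= 1
                )
                if ok:
                    J[r] += p_s * system.beta / m.copy_number
    return OracleSolution(states, pi, index, J, rho, c)


_ORACLE_PRESETS = {}


def _preset(fn):
    _ORACLE_PRESETS[fn.__name__.removeprefix("_preset_")] = fn
    return fn


@_preset
def _preset_two_site_pool():
    m = MRNASpecies("toy", np.array([1, 1]), 1)
    return TranslationSystem(
        mrnas=[m], T=[1], V=[0.7], K=[0.4], kappa=1.3, alpha=0.9, beta=1.1, w=1,
        labels=["t1"],
    )


@_preset
def _preset_alpha_zero():
    m = MRNASpecies("toy", np.array([1, 1]), 1)
    return TranslationSystem(
        mrnas=[m], T=[1], V=[0.7], K=[0.4], kappa=1.3, alpha=0.0, beta=1.1, w=1,
        labels=["t1"],
    )


@_preset
def _preset_l12_fixed():
    m = MRNASpecies("uniform12", np.full(12, 1), 1)
    return TranslationSystem(
        mrnas=[m], T=[100], V=[1.0], K=[1.0], kappa=0.05, alpha=0.6, beta=8.0, w=3,
        infinite_recharge=True, labels=["t1"],
    )


@_preset
def _preset_l6_two_species():
    m = MRNASpecies("alt6", np.array([1, 2, 1, 2, 1, 2]), 1)
    return TranslationSystem(
        mrnas=[m], T=[3, 3], V=[2.0, 2.0], K=[1.0, 1.0], kappa=1.0, alpha=0.8,
        beta=6.0, w=2, labels=["t1", "t2"],
    )


@_preset
def _preset_two_copies_pool():
    m = MRNASpecies("toy3", np.array([1, 1, 1]), 2)
    return TranslationSystem(
        mrnas=[m], T=[2], V=[1.5], K=[0.8], kappa=1.0, alpha=0.7, beta=3.0, w=1,
        labels=["t1"],
    )


def make_oracle_instance(preset: str):
    """Catalogued tiny system plus its exact stationary solution."""
    if preset not in _ORACLE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_ORACLE_PRESETS)}")
    system = _ORACLE_PRESETS[preset]()
    return system, enumerate_ctmc(system)


# ---------------------------------------------------------------------------
# designer-regime presets (three parameter regimes of the two-codon mRNA)


def designer_preset(name: str, n_copies: int = 20, L: int = 45):
    """Two-codon designer systems in each of the three regimes.

    * ``lr1``: slow recharging of the rare central species -> its depletion
      (LR-induced queueing) is reached first;
    * ``qp``: fast recharging -> the central codon's fixed-rate capacity is
      the first bottleneck (sharp queueing-phase transition);
    * ``lr2``: the central species is abundant and the bulk species is
      recharging-limited -> bulk depletion first, no queueing.

    Returns (system, alpha_probe) with alpha_probe safely above the lowest
    predicted threshold.
    """
    mrna = make_designer_mrna(L, 1, 2, n_copies, w=9)
    if name in ("lr1", "qp"):
        T = [1900, 100]
        kappa = 10.0 / 1900  # bulk hops at 10/s, centre at ~0.53/s
        V = [100.0, 0.3] if name == "lr1" else [500.0, 500.0]
    elif name == "lr2":
        T = [600, 1400]
        kappa = 10.0 / 600  # bulk at 10/s, centre fast
        V = [9.0, 100.0]
    else:
        raise ValueError(f"unknown designer preset {name!r}")
    system = TranslationSystem(
        mrnas=[mrna], T=T, V=V, K=[3.0, 3.0], kappa=kappa, alpha=0.0, beta=100.0,
        w=9, labels=["bulk", "center"],
    )
    from .analytics import classify_designer_regime

    probe = 1.6 * classify_designer_regime(system).threshold
    return system.with_alpha(probe), probe


# ---------------------------------------------------------------------------
# packaged synthetic ORFs


_ORF_SEED = 20110


def _sample_codons(rng, n, bias, table, code, allowed):
    codons, p = _codon_probabilities(bias, table, code, allowed=allowed)
    picks = rng.choice(len(codons), size=n, p=p)
    return [codons[j] for j in picks]


def _fast_codon_pool(table: TRNASpeciesTable, code: CodonMap, sigma_min: float = 0.02):
    sigma = table.gene_copy_number / table.gene_copy_number.sum()
    return {c for c in SENSE_CODONS if sigma[code[c] - 1] >= sigma_min}


def packaged_orf_records() -> list:
    """Deterministic synthetic stand-ins for the four yeast ORFs studied
    (correct codon lengths; engineered codon composition).

    * YDR382W_synthetic (110 codons) and YJL136C_synthetic (87): no
      intrinsically slow codons, but one abundant species (Glu2, codon GAA)
      in very high demand with clusters around two thirds of the ORF --
      depletion-driven queueing behind the clusters.
    * YLR378C_synthetic (480): rare-tRNA codons (Arg2, CGG) scattered at
      regular intervals -- isolated intrinsically slow sites.
    * YMR307W_synthetic (560): two rare-codon species, a couple of slow
      sites near the start plus a cluster near the end.

    Returns (name, codon_string_list) pairs; a TAA stop is appended when
    the records are written as FASTA.
    """
    table = load_packaged_trna_table()
    code = load_packaged_codon_map()
    fast = _fast_codon_pool(table, code)
    rng = np.random.default_rng(_ORF_SEED)
    records = []

    def build(name, L, hot, hot_positions, bias=0.85, pool=None):
        pool_ = set(pool or fast)
        pool_.discard(hot)
        body = _sample_codons(rng, L, bias, table, code, pool_)
        for p in hot_positions:
            body[p - 1] = hot
        body[0] = "ATG"
        records.append((name, body))

    # mRNA A-like: 16 scattered + two clusters of 4 around position ~70-79
    scatter_a = list(range(5, 66, 4))[:16]
    clusters_a = [70, 71, 72, 73, 76, 77, 78, 79]
    build("YDR382W_synthetic", 110, "GAA", scatter_a + clusters_a)

    # mRNA B-like: slow CGG every 40 codons
    build("YLR378C_synthetic", 480, "CGG", list(range(30, 480, 40)))

    # mRNA C-like: short, same design family as A
    scatter_c = list(range(5, 50, 5))[:9]
    clusters_c = [56, 57, 58, 60, 61]
    build("YJL136C_synthetic", 87, "GAA", scatter_c + clusters_c)

    # mRNA D-like: slow CGG near the start, GGG scattered + clustered near the end
    body_positions = [25, 60] + list(range(100, 480, 45)) + [500, 510, 520, 521, 522, 523]
    build("YMR307W_synthetic", 560, "GGG", body_positions)
    # overwrite two early sites with the second slow species
    name, body = records[-1]
    body[24] = "CGG"
    body[59] = "CGG"

    return records


def write_orf_fasta(records, path):
    with open(path, "w") as fh:
        for name, body in records:
            seq = "".join(body) + "TAA"
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# cell-cycle multi-species gene set


CELL_CYCLE_GENES = [
    # (name, length_codons, level in G1) -- levels swap in G2
    ("Cln3", 581, "High"),
    ("Cdh1", 567, "High"),
    ("Cdc20", 611, "Low"),
    ("Clb1", 472, "Low"),
    ("Clb6", 381, "High"),
    ("Sic1", 285, "High"),
    ("Cln1", 547, "High"),
    ("Cln2", 546, "High"),
    ("Clb2", 492, "Low"),
    ("Clb5", 436, "High"),
]


def make_cell_cycle_gene_sets(
    seed: int = 7,
    group2_per_tier: int = 20,
    group2_length_range: tuple = (250, 550),
    copies_high: int = 4,
    copies_low: int = 1,
    group2_copies: tuple = (4, 2, 1),
    hot_codon: str = "ATA",
    hot_fraction: float = 0.25,
    background_bias: float = 0.9,
):
    """Reduced 70-species cell-cycle mixture in its two abundance states.

    Ten "group I" genes swap between High and Low abundance from G1 to G2
    (seven are High in G1, three in G2); the G1-High genes share a strong
    demand for one low-supply tRNA (Ile2 via codon ATA by default), so the
    G1 state concentrates demand on that species.  Sixty "group II" genes in
    three abundance tiers keep the same copy numbers in both phases.

    Returns ``{"G1": [...], "G2": [...]}`` of MRNASpecies lists (same gene
    sequences, phase-specific copy numbers).
    """
    table = load_packaged_trna_table()
    code = load_packaged_codon_map()
    rng = np.random.default_rng(seed)

    genes = {}
    for name, L, g1level in CELL_CYCLE_GENES:
        body = _sample_codons(rng, L, background_bias, table, code, None)
        if g1level == "High":
            n_hot = int(round(hot_fraction * L))
            hot_pos = rng.choice(L - 1, size=n_hot, replace=False) + 1
            for p in hot_pos:
                body[p] = hot_codon
        body[0] = "ATG"
        genes[name] = np.array([code[c] for c in body], dtype=np.int64)

    lo, hi = group2_length_range
    tiers = ["high"] * group2_per_tier + ["medhigh"] * group2_per_tier + ["med"] * group2_per_tier
    tier_copies = dict(zip(("high", "medhigh", "med"), group2_copies))
    group2 = []
    for j, tier in enumerate(tiers):
        L = int(rng.integers(lo, hi + 1))
        body = _sample_codons(rng, L, background_bias, table, code, None)
        body[0] = "ATG"
        ids = np.array([code[c] for c in body], dtype=np.int64)
        group2.append((f"g2_{tier}_{j:02d}", ids, tier_copies[tier]))

    out = {}
    for phase in ("G1", "G2"):
        mrnas = []
        for name, L, g1level in CELL_CYCLE_GENES:
            level = g1level if phase == "G1" else ("Low" if g1level == "High" else "High")
            copies = copies_high if level == "High" else copies_low
            mrnas.append(MRNASpecies(name, genes[name], copies))
        for name, ids, copies in group2:
            mrnas.append(MRNASpecies(name, ids, copies))
        out[phase] = mrnas
    return out
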