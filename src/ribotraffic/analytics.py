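"""Closed-form layer: supply/demand metrics, critical initiation rates,
queueing-phase thresholds, regime classification, and the QLI/CAI codon
usage indices.

Model background
----------------
For a uniform mRNA (one codon species, hopping rate k, ribosome width w)
the low-density (LD) phase of the extended-particle exclusion process has

    J(alpha)   = alpha (k - alpha) / (k + (w - 1) alpha)
    rho(alpha) = alpha / (k + (w - 1) alpha),      rho_cov = w rho,

valid up to the maximal-current boundary alpha = k/(1 + sqrt(w)), where the
current saturates at J_max = k/(1 + sqrt(w))^2.

With finite recharging, the charged pool of species i is depleted once its
use rate U_i(alpha) = J(alpha) * N * f_i (hops out of species-i codons per
second, N = total codons, f_i = codon usage fraction) reaches the maximum
recharging rate R_i^max = V_i.  Solving U_i = V_i in the LD current (with
the position-averaged hopping rate) gives the per-species critical
initiation rate alpha_c,i; to first order in V_i/(N f_i k),
alpha_c,i ~ V_i/(N f_i), which is proportional to 1/Q_i when enzyme
numbers scale with tRNA numbers -- the species with the largest
demand/supply ratio Q_i = f_i/sigma_i is the predicted bottleneck.

A fixed-rate bottleneck (a single slow codon of rate q in a bulk of rate k)
instead causes a sharp queueing-phase (QP) transition once the LD current
exceeds the slow site's carrying capacity q/(1 + sqrt(w))^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import TranslationSystem

logger = logging.getLogger(__name__)

__all__ = [
    "LDResult",
    "AnalyticsResult",
    "supply_demand",
    "ld_theory",
    "ld_alpha_for_current",
    "use_rate",
    "critical_alphas",
    "alpha_star",
    "qp_threshold",
    "classify_designer_regime",
    "GENETIC_CODE_FAMILIES",
    "rscu_weights",
    "cai",
    "qli",
]


# ---------------------------------------------------------------------------
# supply / demand


def supply_demand(system: TranslationSystem):
    """Per-species tRNA supply sigma_i = T_i/T_tot, codon demand
    f_i = sum_r m_r n_{i,r} / N, and the queueing propensity Q_i = f_i/sigma_i.
    """
    sigma = system.T.astype(float) / system.T_tot
    counts = system.codon_counts().astype(float)
    f = counts / counts.sum()
    Q = f / sigma
    return sigma, f, Q


# ---------------------------------------------------------------------------
# LD closed forms


@dataclass(frozen=True)
class LDResult:
    J: float
    rho: float
    rho_cov: float
    in_ld_domain: bool


def ld_boundary(k: float, w: int) -> float:
    """Initiation rate of the LD -> maximal-current transition."""
    return k / (1.0 + np.sqrt(w))


def ld_theory(alpha: float, k: float, w: int) -> LDResult:
    """LD-phase current and densities for a uniform lattice."""
    if alpha < 0 or k <= 0 or w < 1:
        raise ValueError("alpha >= 0, k > 0, w >= 1 required")
    denom = k + (w - 1.0) * alpha
    J = alpha * (k - alpha) / denom
    rho = alpha / denom
    return LDResult(float(J), float(rho), float(w * rho), bool(alpha <= ld_boundary(k, w)))


def ld_alpha_for_current(C: float, k: float, w: int) -> float:
    """Smallest initiation rate at which the LD current reaches C.

    Returns inf when C exceeds the maximal LD current k/(1+sqrt(w))^2
    (the demand can never be met within the LD phase).
    """
    if C <= 0:
        return 0.0
    cap = k / (1.0 + np.sqrt(w)) ** 2
    if C > cap * (1.0 + 1e-12):
        return float("inf")
    bcoef = k - C * (w - 1.0)
    disc = max(bcoef * bcoef - 4.0 * C * k, 0.0)
    return float((bcoef - np.sqrt(disc)) / 2.0)


# ---------------------------------------------------------------------------
# critical initiation rates


def _mean_supply_rate(system: TranslationSystem, averaging: str = "arithmetic") -> float:
    """Position-averaged fully-charged hopping rate <k> over all codons
    (copy-weighted).  The arithmetic mean is the default; a harmonic option
    is kept for sensitivity checks."""
    k_i = system.hopping_rates()
    counts = system.codon_counts().astype(float)
    fweights = counts / counts.sum()
    if averaging == "arithmetic":
        return float(np.dot(fweights, k_i))
    if averaging == "harmonic":
        return float(1.0 / np.dot(fweights, 1.0 / k_i))
    raise ValueError(averaging)


def use_rate(system: TranslationSystem, alpha: float, averaging: str = "arithmetic") -> np.ndarray:
    """U_i(alpha): rate at which species-i aa-tRNAs are consumed in the LD
    phase, J(alpha) * sum_r m_r n_{i,r} (assuming full charging)."""
    kbar = _mean_supply_rate(system, averaging)
    J = ld_theory(alpha, kbar, system.w).J
    return J * system.codon_counts().astype(float)


@dataclass
class AnalyticsResult:
    labels: list
    sigma: np.ndarray
    f: np.ndarray
    Q: np.ndarray
    R_max: np.ndarray
    alpha_c: np.ndarray            # per-species critical initiation rate
    alpha_c_first_order: np.ndarray
    k_mean: float
    alpha_star: float | None       # mono-codon LR onset, when applicable
    bottleneck_index: int | None   # 0-based argmin alpha_c, None if none finite
    qli: dict = field(default_factory=dict)
    cai: dict = field(default_factory=dict)

    @property
    def bottleneck_label(self):
        return None if self.bottleneck_index is None else self.labels[self.bottleneck_index]

    def summary_dict(self) -> dict:
        out = {"k_mean": float(self.k_mean)}
        if self.alpha_star is not None:
            out["alpha_star"] = float(self.alpha_star)
        if self.bottleneck_index is not None:
            out["bottleneck_species"] = self.bottleneck_label
            out["alpha_c"] = float(self.alpha_c[self.bottleneck_index])
        for name, v in self.qli.items():
            out[f"QLI_{name}"] = float(v)
        for name, v in self.cai.items():
            out[f"CAI_{name}"] = float(v)
        return out


def critical_alphas(system: TranslationSystem, averaging: str = "arithmetic") -> AnalyticsResult:
    """Predict, per tRNA species, the initiation rate at which its use rate
    meets its maximum recharging rate, and the overall bottleneck species.

    Species whose demand never reaches V_i within the LD phase get
    alpha_c = inf (they will never become depleted).
    """
    sigma, f, Q = supply_demand(system)
    N = system.n_codons_total
    kbar = _mean_supply_rate(system, averaging)
    S = system.n_species
    alpha_c = np.full(S, np.inf)
    first = np.full(S, np.inf)
    for i in range(S):
        if f[i] <= 0:
            continue
        C = system.V[i] / (N * f[i])
        alpha_c[i] = ld_alpha_for_current(C, kbar, system.w)
        first[i] = C
    finite = np.isfinite(alpha_c)
    bottleneck = int(np.argmin(alpha_c)) if finite.any() else None
    used = f > 0
    a_star = None
    if used.sum() == 1:
        i = int(np.flatnonzero(used)[0])
        a_star = alpha_star(system.kappa * system.T[i], float(system.V[i]), N, system.w)
    return AnalyticsResult(
        labels=list(system.labels),
        sigma=sigma,
        f=f,
        Q=Q,
        R_max=system.V.copy(),
        alpha_c=alpha_c,
        alpha_c_first_order=first,
        k_mean=kbar,
        alpha_star=a_star,
        bottleneck_index=bottleneck,
    )


def alpha_star(k: float, V: float, N: int, w: int) -> float:
    """Mono-codon limited-resources onset: initiation rate at which the
    total tRNA use rate N*J(alpha) reaches the maximum recharging rate V."""
    return ld_alpha_for_current(V / N, k, w)


# ---------------------------------------------------------------------------
# fixed-rate queueing phase


def bottleneck_capacity(q: float, k: float, w: int) -> float:
    """Maximal current through a single site of rate q in a bulk of rate k.

    Renewal picture: each passage costs the slow-site service time 1/q plus
    the headway time for the follower to close the w-codon gap; the headway
    constant ((1+sqrt(w))^2 - 1)/k is fixed by requiring that q = k recover
    the uniform-lattice maximal current k/(1+sqrt(w))^2.  The q -> 0 limit
    is exact (capacity -> q).  Validated against exact CTMC enumeration of
    a single-defect lattice (see the test suite).
    """
    if q <= 0 or k <= 0:
        raise ValueError("rates must be positive")
    headway = ((1.0 + np.sqrt(w)) ** 2 - 1.0) / k
    return 1.0 / (1.0 / q + headway)


def qp_threshold(q: float, k: float, w: int) -> float:
    """Initiation rate beyond which ribosomes queue behind a single slow
    site of rate q embedded in a bulk of rate k (fixed hopping rates).

    Queueing starts when the LD current of the bulk exceeds the slow site's
    carrying capacity.  For q >= k the site is not a bottleneck and inf is
    returned; at q = k the threshold reduces to the uniform-lattice LD
    boundary k/(1+sqrt(w)).
    """
    if q <= 0 or k <= 0:
        raise ValueError("rates must be positive")
    if q > k:
        return float("inf")
    return ld_alpha_for_current(bottleneck_capacity(q, k, w), k, w)


@dataclass(frozen=True)
class DesignerRegime:
    region: str  # "LR1_queueing" | "QP" | "LR2_no_queueing"
    alpha_c_center: float
    alpha_qp: float
    alpha_c_bulk: float

    @property
    def threshold(self) -> float:
        return min(self.alpha_c_center, self.alpha_qp, self.alpha_c_bulk)


def classify_designer_regime(system: TranslationSystem) -> DesignerRegime:
    """Classify a two-codon designer mRNA (uniform bulk species, one distinct
    central codon) by whichever transition is reached first as alpha grows:

    * depletion of the rare central species -> smooth LR-induced queueing,
    * the fixed-rate capacity of the central codon -> sharp QP transition,
    * depletion of the bulk species -> LR regime with no queueing (the slow
      codons then make up the bulk of the mRNA, including its start).
    """
    sigma, f, Q = supply_demand(system)
    used = np.flatnonzero(f > 0)
    if used.size != 2:
        raise ValueError("designer classification needs exactly two codon species in use")
    bulk_i, center_i = (used[0], used[1]) if f[used[0]] > f[used[1]] else (used[1], used[0])
    res = critical_alphas(system)
    k = system.hopping_rates()
    a_qp = qp_threshold(float(k[center_i]), float(k[bulk_i]), system.w)
    a_center = float(res.alpha_c[center_i])
    a_bulk = float(res.alpha_c[bulk_i])
    order = np.argmin([a_center, a_qp, a_bulk])
    region = ("LR1_queueing", "QP", "LR2_no_queueing")[int(order)]
    return DesignerRegime(region, a_center, a_qp, a_bulk)


# ---------------------------------------------------------------------------
# codon usage indices


def _families():
    """Synonymous codon families of the standard genetic code (DNA, sense
    codons only)."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1].forward_table
    fams = {}
    for codon, aa in table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}


GENETIC_CODE_FAMILIES = _families()


def rscu_weights(reference_counts: dict, pseudocount: float = 0.5):
    """Relative synonymous codon usage and relative adaptiveness weights
    from codon counts of a highly-expressed reference gene set.

    RSCU_j = X_j / mean(X over the synonymous family); the CAI weight is
    X_j / max(X over the family).  Zero counts receive the pseudocount
    (logged), so every weight is positive.
    """
    rscu, weights = {}, {}
    n_pseudo = 0
    for aa, fam in GENETIC_CODE_FAMILIES.items():
        X = np.array([float(reference_counts.get(c, 0.0)) for c in fam])
        if np.any(X == 0):
            n_pseudo += int(np.sum(X == 0))
            X = np.where(X == 0, pseudocount, X)
        for c, x in zip(fam, X):
            rscu[c] = x / X.mean()
            weights[c] = x / X.max()
    if n_pseudo:
        logger.info("rscu_weights: pseudocount %.2f applied to %d zero-count codons",
                    pseudocount, n_pseudo)
    return rscu, weights


def cai(codons: list, weights: dict, exclude_single_codon_families: bool = True) -> float:
    """Codon adaptation index: geometric mean of the relative adaptiveness
    weights over the codon positions of one ORF (DNA codon strings).

    Single-codon families (Met, Trp) carry no synonymous information and are
    excluded by default, following standard practice.
    """
    single = {fam[0] for fam in GENETIC_CODE_FAMILIES.values() if len(fam) == 1}
    logs = []
    for c in codons:
        c = c.upper().replace("U", "T")
        if exclude_single_codon_families and c in single:
            continue
        if c not in weights:
            raise ValueError(f"no RSCU weight for codon {c!r}")
        logs.append(np.log(weights[c]))
    if not logs:
        raise ValueError("no informative codons for CAI")
    return float(np.exp(np.mean(logs)))


def qli(codon_ids: np.ndarray, Q: np.ndarray, zero_policy: float = 0.5) -> float:
    """Queueing likelihood index: geometric mean of the demand/supply ratio
    Q over the codon positions of one ORF (1-based tRNA species ids).

    A zero Q (species unused in the demand reference) is replaced by
    zero_policy times the smallest positive Q, and the substitution is
    logged.
    """
    codon_ids = np.asarray(codon_ids, dtype=np.int64)
    Q = np.asarray(Q, dtype=float)
    vals = Q[codon_ids - 1]
    if np.any(vals <= 0):
        floor = zero_policy * Q[Q > 0].min()
        logger.info("qli: %d zero-Q codons floored at %.3g", int(np.sum(vals <= 0)), floor)
        vals = np.where(vals <= 0, floor, vals)
    return float(np.exp(np.mean(np.log(vals))))
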