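"""Cell-to-simulation parameter scaling.

Simulated systems are far smaller than a cell, so every extensive quantity
is scaled by the ratio of simulated to cellular codon totals: the tRNA pool
preserves the cellular tRNA-per-codon ratio, enzyme numbers preserve the
synthetase-per-tRNA ratio, and concentrations are converted to molecule
numbers through the *effective volume* -- the volume a cell would have if it
were shrunk by the same factor as the codon count.  All intensive
predictions (sigma, f, Q, critical initiation rates) are invariant under
this scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .core import TranslationSystem
from .io import TRNASpeciesTable, packaged_path

__all__ = [
    "AVOGADRO",
    "KineticsParams",
    "SystemConfig",
    "load_defaults",
    "allocate_trna_counts",
    "calibrate_kappa",
    "enzyme_kinetics",
    "build_system",
]

AVOGADRO = 6.02214076e23


def load_defaults(path=None) -> dict:
    """Load the documented defaults file (packaged unless a path is given)."""
    path = Path(path) if path is not None else packaged_path("defaults.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class KineticsParams:
    """Rate parameters of one run.

    kappa is the hopping-rate constant per charged molecule (the
    proportionality constant between a codon's hopping rate and its charged
    pool size); it is usually calibrated from ``k_mean_target`` rather than
    set directly.
    """

    kappa: float
    w: int
    alpha: float
    beta: float
    k_mean_target: float

    def validate(self, T: np.ndarray):
        if min(self.kappa, self.beta, self.k_mean_target) <= 0 or self.alpha < 0:
            raise ValueError("rates must be positive (alpha may be zero)")
        if self.w < 1:
            raise ValueError("ribosome width must be >= 1 codon")
        kmax = self.kappa * float(np.max(T))
        if self.beta <= self.alpha or self.beta <= kmax:
            raise ValueError(
                f"termination must be non-limiting: beta={self.beta} vs "
                f"alpha={self.alpha}, max hopping rate {kmax:.4g}"
            )


@dataclass
class SystemConfig:
    """Cell-reference totals and the simulated system size."""

    n_codons_target: int
    cell_codons: float = 1.3e7
    cell_trnas: float = 2.9e6
    cell_volume_litres: float = 4.2e-14
    trna_per_codon_ratio: float | None = None
    enzymes_per_trna: float = 0.18
    kcat: float = 10.0
    km_molar: float = 3.0e-7
    burn_in_time: float = 200.0
    measure_time: float = 400.0
    seed: int = 1

    def __post_init__(self):
        if self.trna_per_codon_ratio is None:
            self.trna_per_codon_ratio = self.cell_trnas / self.cell_codons
        if self.n_codons_target < 1:
            raise ValueError("n_codons_target must be positive")

    def v_eff_litres(self, n_codons_sim: int | None = None) -> float:
        """Effective volume: cell volume scaled by the codon reduction."""
        n = self.n_codons_target if n_codons_sim is None else n_codons_sim
        return self.cell_volume_litres * n / self.cell_codons

    def trna_total(self, n_codons_sim: int | None = None) -> int:
        n = self.n_codons_target if n_codons_sim is None else n_codons_sim
        return int(round(self.trna_per_codon_ratio * n))

    @classmethod
    def from_defaults(cls, n_codons_target: int, defaults: dict | None = None, **over):
        d = defaults if defaults is not None else load_defaults()
        kw = dict(
            n_codons_target=n_codons_target,
            cell_codons=float(d["cell"]["codons"]),
            cell_trnas=float(d["cell"]["trnas"]),
            cell_volume_litres=float(d["cell"]["volume_litres"]),
            enzymes_per_trna=float(d["enzymes"]["enzymes_per_trna"]),
            kcat=float(d["enzymes"]["kcat"]),
            km_molar=float(d["enzymes"]["km_molar"]),
            burn_in_time=float(d["schedule"]["burn_in"]),
            measure_time=float(d["schedule"]["measure"]),
        )
        kw.update(over)
        return cls(**kw)


def allocate_trna_counts(g: np.ndarray, T_tot: int) -> np.ndarray:
    """Split a tRNA total over species proportionally to gene copy numbers.

    Largest-remainder rounding; the result sums to ``T_tot`` exactly and
    every species receives at least one molecule.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("gene copy numbers must be positive")
    S = g.size
    if T_tot < S:
        raise ValueError(f"T_tot={T_tot} too small to give each of {S} species one molecule")
    raw = g / g.sum() * T_tot
    base = np.floor(raw).astype(np.int64)
    rem = raw - base
    short = int(T_tot - base.sum())
    # stable largest-remainder: ties broken by species order
    order = np.lexsort((np.arange(S), -rem))
    base[order[:short]] += 1
    # enforce the one-molecule floor, taking from the most populous species
    while np.any(base == 0):
        base[np.argmax(base)] -= 1
        base[np.argmin(base)] += 1
    assert base.sum() == T_tot
    return base


def calibrate_kappa(
    T: np.ndarray, k_mean_target: float, weights: np.ndarray | None = None
) -> float:
    """Fix kappa such that the mean fully-charged hopping rate equals the
    target.

    The default is the unweighted mean over tRNA species,
    ``mean_i(kappa * T_i) = k_mean_target``; passing codon-usage ``weights``
    (summing to 1) switches to the usage-weighted mean.
    """
    T = np.asarray(T, dtype=float)
    if k_mean_target <= 0:
        raise ValueError("target mean hopping rate must be positive")
    if T.sum() <= 0:
        raise ValueError("tRNA counts must be positive")
    if weights is None:
        return k_mean_target * T.size / float(T.sum())
    weights = np.asarray(weights, dtype=float)
    return k_mean_target / float(np.dot(weights, T))


def enzyme_kinetics(
    kcat: float,
    enzymes_per_trna: float,
    T: np.ndarray,
    km_molar: float,
    v_eff_litres: float,
):
    """Per-species synthetase parameters under the uniform-enzyme assumption.

    Returns ``(V, E, K)``: enzyme counts ``E_i = round(e * T_i)`` (at least
    one molecule), maximum charging rates ``V_i = kcat * E_i`` and the
    Michaelis constant converted to molecules through the effective volume
    (identical for every species).
    """
    if min(kcat, enzymes_per_trna, km_molar, v_eff_litres) <= 0:
        raise ValueError("enzyme kinetic inputs must be positive")
    T = np.asarray(T, dtype=float)
    E = np.maximum(1, np.round(enzymes_per_trna * T)).astype(np.int64)
    V = kcat * E.astype(float)
    K = np.full(T.size, km_molar * AVOGADRO * v_eff_litres, dtype=float)
    return V, E, K


def build_system(
    table: TRNASpeciesTable,
    mrnas: list,
    config: SystemConfig,
    kinetics: dict | None = None,
    alpha: float = 0.1,
    infinite_recharge: bool = False,
) -> TranslationSystem:
    """Assemble a TranslationSystem from a tRNA table, an mRNA set with copy
    numbers, and the scaling configuration.

    The tRNA total follows the cellular tRNA-per-codon ratio applied to the
    *actual* simulated codon count (not the target), so scaling invariance
    holds exactly.
    """
    defaults = load_defaults()["kinetics"]
    kin = dict(
        w=int(defaults["ribosome_width_codons"]),
        k_mean_target=float(defaults["mean_hopping_rate"]),
        beta=float(defaults["termination_rate"]),
        kappa=None,
        kappa_weighting="species",
    )
    if kinetics:
        kin.update(kinetics)

    n_codons = int(sum(m.copy_number * m.length for m in mrnas))
    T_tot = config.trna_total(n_codons)
    T = allocate_trna_counts(table.gene_copy_number, T_tot)
    if kin["kappa"] is None:
        if kin["kappa_weighting"] == "usage":
            counts = np.zeros(table.n_species, dtype=float)
            for m in mrnas:
                counts += m.copy_number * m.codon_counts(table.n_species)
            kappa = calibrate_kappa(T, kin["k_mean_target"], counts / counts.sum())
        else:
            kappa = calibrate_kappa(T, kin["k_mean_target"])
    else:
        kappa = float(kin["kappa"])
    V, E, K = enzyme_kinetics(
        config.kcat, config.enzymes_per_trna, T, config.km_molar, config.v_eff_litres(n_codons)
    )
    table.T, table.E, table.kcat, table.V, table.K = T, E, config.kcat, V, K
    system = TranslationSystem(
        mrnas=list(mrnas),
        T=T,
        V=V,
        K=K,
        kappa=kappa,
        alpha=alpha,
        beta=float(kin["beta"]),
        w=int(kin["w"]),
        infinite_recharge=infinite_recharge,
        labels=list(table.labels),
    )
    system.validate_rates()
    return system
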