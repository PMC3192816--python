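"""Core containers shared by every layer of the package.

The model couples M copies of one or more mRNA "lattices" to a single finite
pool of tRNAs.  A ribosome occupies ``w`` consecutive codons but decodes only
the rightmost covered codon (its *reader*).  The hopping rate off a codon of
tRNA species ``i`` is ``kappa * a_i(t)`` where ``a_i`` is the instantaneous
number of charged (aminoacylated) tRNAs of that species; every hop consumes
one charged tRNA, and bare tRNAs are recharged by a Michaelis--Menten channel
with per-species maximum rate ``V_i`` and half-saturation constant ``K_i``
(in molecules).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MRNASpecies", "TranslationSystem"]


@dataclass(frozen=True)
class MRNASpecies:
    """One mRNA species: a codon sequence (as 1-based tRNA species ids),
    its cellular copy number and its initiation/termination rates.

    ``alpha``/``beta`` may be None, in which case the system-level rates
    apply.
    """

    name: str
    codons: np.ndarray
    copy_number: int = 1

    def __post_init__(self):
        codons = np.asarray(self.codons, dtype=np.int64)
        object.__setattr__(self, "codons", codons)
        if codons.ndim != 1 or codons.size == 0:
            raise ValueError(f"{self.name}: codon sequence must be a non-empty 1D array")
        if codons.min() < 1:
            raise ValueError(f"{self.name}: tRNA species ids are 1-based positive integers")
        if self.copy_number < 1:
            raise ValueError(f"{self.name}: copy_number must be >= 1")

    @property
    def length(self) -> int:
        return int(self.codons.size)

    def codon_counts(self, n_species: int) -> np.ndarray:
        """n_i: number of codons of each tRNA species on this mRNA."""
        return np.bincount(self.codons - 1, minlength=n_species).astype(np.int64)


@dataclass
class TranslationSystem:
    """A complete simulation system: mRNA set plus the shared tRNA pool.

    Parameters
    ----------
    mrnas : list of MRNASpecies
    T : array of int
        Total number of tRNA molecules per species (charged + bare).
    V : array of float
        Maximum recharging rate per species (molecules/s), ``V_i = kcat * E_i``.
    K : array of float
        Michaelis constant per species in molecules.
    kappa : float
        Hopping-rate constant per charged molecule (1/s per molecule).
    alpha, beta : float
        Initiation and termination rates (1/s); termination is assumed
        non-limiting (beta larger than every hopping rate).
    w : int
        Ribosome width in codons.
    infinite_recharge : bool
        If True the charging dynamics are switched off: hopping rates are
        fixed at ``kappa * T_i`` (the classic extended-particle TASEP).
    termination_consumes_trna : bool
        Whether the terminal hop (rate beta, out of the last codon) consumes
        a charged tRNA of the last codon's species.
    """

    mrnas: list
    T: np.ndarray
    V: np.ndarray
    K: np.ndarray
    kappa: float
    alpha: float
    beta: float
    w: int
    infinite_recharge: bool = False
    termination_consumes_trna: bool = True
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.int64)
        self.V = np.asarray(self.V, dtype=np.float64)
        self.K = np.asarray(self.K, dtype=np.float64)
        S = self.T.size
        if not (self.V.size == S and self.K.size == S):
            raise ValueError("T, V, K must have one entry per tRNA species")
        if np.any(self.T < 0) or np.any(self.V < 0) or np.any(self.K <= 0):
            raise ValueError("tRNA counts must be >= 0, V >= 0, K > 0")
        if self.kappa <= 0 or self.alpha < 0 or self.beta <= 0 or self.w < 1:
            raise ValueError("rates must be positive (alpha may be 0) and w >= 1")
        for m in self.mrnas:
            if m.length < self.w:
                raise ValueError(f"{m.name}: mRNA shorter than the ribosome width")
            if m.codons.max() > S:
                raise ValueError(f"{m.name}: codon refers to unknown tRNA species")
        if not self.labels:
            self.labels = [f"t{i + 1}" for i in range(S)]

    # -- derived quantities -------------------------------------------------

    @property
    def n_species(self) -> int:
        return int(self.T.size)

    @property
    def T_tot(self) -> int:
        return int(self.T.sum())

    @property
    def n_lattices(self) -> int:
        return int(sum(m.copy_number for m in self.mrnas))

    @property
    def n_codons_total(self) -> int:
        """N: total number of codons over all mRNA copies."""
        return int(sum(m.copy_number * m.length for m in self.mrnas))

    def codon_counts(self) -> np.ndarray:
        """Copy-weighted codon counts per tRNA species: sum_r m_r * n_{i,r}."""
        out = np.zeros(self.n_species, dtype=np.int64)
        for m in self.mrnas:
            out += m.copy_number * m.codon_counts(self.n_species)
        return out

    def hopping_rates(self) -> np.ndarray:
        """Fully charged hopping rate per species, k_i = kappa * T_i."""
        return self.kappa * self.T.astype(float)

    def with_alpha(self, alpha: float) -> "TranslationSystem":
        return replace(self, alpha=alpha)

    def validate_rates(self):
        """Termination must not be limiting: beta > alpha and beta > max k_i."""
        kmax = float(self.hopping_rates().max())
        if self.beta <= self.alpha or self.beta <= kmax:
            raise ValueError(
                f"beta={self.beta} must exceed alpha={self.alpha} "
                f"and the largest hopping rate {kmax:.3g}"
            )
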