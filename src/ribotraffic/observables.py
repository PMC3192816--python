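"""Steady-state observables from accumulated trajectory statistics.

All quantities are time-weighted averages over the measurement window:
currents (protein production rates per mRNA), reader and coverage density
profiles, relative charging levels, bound ribosomes per codon, and per-site
fluxes.  Standard errors come from block averaging (the measurement window
is split into equal blocks treated as independent samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ObservableSet", "current", "density_profiles", "charging_levels"]


def current(termination_counts, time: float, m_r: int) -> float:
    """Protein production rate per mRNA copy: terminations / (time * copies)."""
    if time <= 0:
        raise ValueError("measurement window must be positive")
    return float(np.sum(termination_counts)) / (time * m_r)


def density_profiles(occupancy_integral: np.ndarray, w: int, time: float, m_r: int):
    """Reader and coverage density profiles from a per-site dwell integral.

    The coverage at site j sums the reader density over the w sites
    [j, j+w-1] that place any part of a ribosome on j (readers sit at the
    rightmost covered codon; entering/exiting footprints overhang the
    lattice ends).
    """
    if time <= 0:
        raise ValueError("measurement window must be positive")
    reader = np.asarray(occupancy_integral, dtype=float) / (time * m_r)
    L = reader.size
    cov = np.zeros(L)
    # suffix-sum window: cov[j] = sum(reader[j : j+w])
    cs = np.concatenate([np.cumsum(reader), np.full(w, np.sum(reader))])
    cov = cs[np.minimum(np.arange(L) + w - 1, L - 1)] - np.concatenate([[0.0], cs[: L - 1]])
    return reader, cov


def charging_levels(charge_integral: np.ndarray, T: np.ndarray, time: float) -> np.ndarray:
    """c_i: time-averaged charged fraction of each tRNA species."""
    if time <= 0:
        raise ValueError("measurement window must be positive")
    return np.asarray(charge_integral, dtype=float) / (time * np.asarray(T, dtype=float))


def _block_se(block_values: np.ndarray) -> float:
    n = block_values.size
    if n < 2:
        return float("nan")
    return float(np.std(block_values, ddof=1) / np.sqrt(n))


@dataclass
class ObservableSet:
    """Complete measured output of one steady-state run."""

    mrna_names: list
    copy_numbers: np.ndarray
    lengths: np.ndarray
    w: int
    t_meas: float
    n_blocks: int
    trna_labels: list

    J: np.ndarray                 # per mRNA species, proteins/mRNA/s
    J_se: np.ndarray
    reader_profiles: dict         # name -> rho(j)
    coverage_profiles: dict       # name -> rho_cov(j)
    flux_profiles: dict           # name -> hops past each site /mRNA/s
    flux_se_profiles: dict
    c: np.ndarray                 # charging level per tRNA species
    c_se: np.ndarray
    ribosomes_per_codon: float
    ribosomes_per_codon_se: float
    total_bound_ribosomes: float
    consumption_rate: np.ndarray  # charged-tRNA consumptions /s per species
    seed: int | None = None
    blocks: dict = field(default_factory=dict)  # raw per-block integrals

    # -- per-species scalars ------------------------------------------------

    def mean_reader_density(self, name: str) -> float:
        return float(np.mean(self.reader_profiles[name]))

    def mean_coverage_density(self, name: str) -> float:
        return float(np.mean(self.coverage_profiles[name]))

    def current_of(self, name: str) -> float:
        return float(self.J[self.mrna_names.index(name)])

    # -- frames / summaries --------------------------------------------------

    def profile_frame(self, name: str) -> pd.DataFrame:
        rho = self.reader_profiles[name]
        return pd.DataFrame(
            {
                "position": np.arange(1, rho.size + 1),
                "reader_density": rho,
                "coverage_density": self.coverage_profiles[name],
                "flux": self.flux_profiles[name],
            }
        )

    def charging_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.trna_labels,
                "charging_level": self.c,
                "se": self.c_se,
                "consumption_rate": self.consumption_rate,
            }
        )

    def summary_dict(self) -> dict:
        out = {
            "t_meas": float(self.t_meas),
            "n_blocks": int(self.n_blocks),
            "ribosomes_per_codon": float(self.ribosomes_per_codon),
            "ribosomes_per_codon_se": float(self.ribosomes_per_codon_se),
            "total_bound_ribosomes": float(self.total_bound_ribosomes),
        }
        if self.seed is not None:
            out["seed"] = int(self.seed)
        for i, name in enumerate(self.mrna_names):
            out[f"J_{name}"] = float(self.J[i])
            out[f"J_se_{name}"] = float(self.J_se[i])
            out[f"rho_{name}"] = self.mean_reader_density(name)
            out[f"rho_cov_{name}"] = self.mean_coverage_density(name)
        out["c_min"] = float(np.min(self.c))
        out["c_min_species"] = self.trna_labels[int(np.argmin(self.c))]
        return out

    def stationarity_gap(self) -> float:
        """|first-half - second-half| current, in units of the block SE
        (used as a steady-state sanity check)."""
        term = self.blocks.get("term")
        if term is None or self.n_blocks < 4:
            return float("nan")
        tot = term.sum(axis=1)
        h = self.n_blocks // 2
        first, second = tot[:h].mean(), tot[h : 2 * h].mean()
        se = np.std(tot[: 2 * h], ddof=1) / np.sqrt(h)
        if se == 0:
            return 0.0 if first == second else float("inf")
        return float(abs(first - second) / se)


def assemble(system, schedule, seed, occ, hops, term, charge_int, rib_int, consumed):
    """Build an ObservableSet from raw kernel accumulators."""
    t_meas = float(schedule.measure)
    nb = int(schedule.n_blocks)
    names = [m.name for m in system.mrnas]
    ms = np.array([m.copy_number for m in system.mrnas], dtype=np.int64)
    Ls = np.array([m.length for m in system.mrnas], dtype=np.int64)
    off = np.concatenate([[0], np.cumsum(Ls)])

    J = term.sum(axis=0) / (t_meas * ms)
    blk_len = t_meas / nb
    J_se = np.array([_block_se(term[:, r] / (blk_len * ms[r])) for r in range(len(names))])

    reader_profiles, coverage_profiles, flux_profiles, flux_se_profiles = {}, {}, {}, {}
    for r, name in enumerate(names):
        occ_r = occ[:, off[r] : off[r + 1]]
        reader, cov = density_profiles(occ_r.sum(axis=0), system.w, t_meas, ms[r])
        reader_profiles[name] = reader
        coverage_profiles[name] = cov
        hops_r = hops[:, off[r] : off[r + 1]]
        flux_profiles[name] = hops_r.sum(axis=0) / (t_meas * ms[r])
        fb = hops_r / (blk_len * ms[r])
        flux_se_profiles[name] = (
            np.std(fb, axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full(fb.shape[1], np.nan)
        )

    c = charging_levels(charge_int.sum(axis=0), system.T, t_meas)
    cb = charge_int / (blk_len * system.T.astype(float))
    c_se = np.std(cb, axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full(c.size, np.nan)

    N = system.n_codons_total
    rpc_blocks = rib_int[:, 0] / (blk_len * N)
    rpc = float(rib_int.sum() / (t_meas * N))

    return ObservableSet(
        mrna_names=names,
        copy_numbers=ms,
        lengths=Ls,
        w=system.w,
        t_meas=t_meas,
        n_blocks=nb,
        trna_labels=list(system.labels),
        J=J,
        J_se=J_se,
        reader_profiles=reader_profiles,
        coverage_profiles=coverage_profiles,
        flux_profiles=flux_profiles,
        flux_se_profiles=flux_se_profiles,
        c=c,
        c_se=c_se,
        ribosomes_per_codon=rpc,
        ribosomes_per_codon_se=_block_se(rpc_blocks),
        total_bound_ribosomes=rpc * N,
        consumption_rate=consumed.sum(axis=0) / t_meas,
        seed=seed,
        blocks={"term": term, "charge": charge_int, "rib": rib_int, "hops": hops, "occ": occ},
    )
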