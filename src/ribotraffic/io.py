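"""Reading and writing of every external artifact.

Formats
-------
* ORFs: FASTA (DNA or RNA alphabet, case-insensitive), terminal stop codon
  trimmed before mapping -- stop codons are not lattice sites, termination
  replaces stop-codon decoding.
* tRNA species table: TSV with columns ``id, label, anticodon, amino_acid,
  gene_copy_number``.
* Codon map: TSV with columns ``codon, species_id`` covering exactly the 61
  sense codons.
* Results: per-mRNA density-profile TSVs plus a key-value summary file, all
  round-trip readable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import MRNASpecies

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "CodonMap",
    "NamedCodonSequence",
    "TRNASpeciesTable",
    "read_orf_fasta",
    "load_trna_table",
    "load_codon_map",
    "packaged_path",
    "load_packaged_trna_table",
    "load_packaged_codon_map",
    "write_results",
    "read_results",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES = "TCAG"
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)


def _norm_codon(codon: str) -> str:
    return codon.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class CodonMap:
    """Mapping from sense codon to tRNA species id (1..S), one species per
    codon (wobble base pairing is deliberately not modelled)."""

    mapping: dict

    def __post_init__(self):
        norm = {_norm_codon(c): int(s) for c, s in self.mapping.items()}
        object.__setattr__(self, "mapping", norm)
        missing = set(SENSE_CODONS) - set(norm)
        extra = set(norm) - set(SENSE_CODONS)
        if missing:
            raise ValueError(f"codon map misses sense codons: {sorted(missing)}")
        if extra & STOP_CODONS:
            raise ValueError("codon map must not assign stop codons")
        if extra:
            raise ValueError(f"codon map contains invalid codons: {sorted(extra)}")
        if min(norm.values()) < 1:
            raise ValueError("species ids are 1-based positive integers")

    def __getitem__(self, codon: str) -> int:
        return self.mapping[_norm_codon(codon)]

    def __contains__(self, codon: str) -> bool:
        return _norm_codon(codon) in self.mapping

    @property
    def n_species_referenced(self) -> int:
        return len(set(self.mapping.values()))

    def check_against_table(self, table: "TRNASpeciesTable"):
        ids = set(self.mapping.values())
        known = set(range(1, table.n_species + 1))
        if not ids <= known:
            raise ValueError(f"codon map references unknown species ids {sorted(ids - known)}")

    @classmethod
    def from_tsv(cls, path) -> "CodonMap":
        df = pd.read_csv(path, sep="\t")
        for col in ("codon", "species_id"):
            if col not in df.columns:
                raise ValueError(f"codon map {path}: missing column {col!r}")
        return cls(dict(zip(df["codon"], df["species_id"])))


@dataclass(frozen=True)
class NamedCodonSequence:
    """An ORF mapped to tRNA-species ids; positions are 1-based left to right."""

    name: str
    codons: np.ndarray  # int64, values in 1..S

    def __post_init__(self):
        object.__setattr__(self, "codons", np.asarray(self.codons, dtype=np.int64))

    @property
    def length(self) -> int:
        return int(self.codons.size)

    def to_mrna(self, copy_number: int = 1) -> MRNASpecies:
        return MRNASpecies(self.name, self.codons, copy_number)


@dataclass
class TRNASpeciesTable:
    """Per-species tRNA bookkeeping.

    Gene copy numbers come from the genome; molecule totals ``T``, enzyme
    counts ``E``, maximum charging rates ``V = kcat * E`` and Michaelis
    constants ``K`` (molecules) are populated by the parameterization layer.
    """

    labels: list
    anticodons: list
    amino_acids: list
    gene_copy_number: np.ndarray
    T: np.ndarray | None = None
    E: np.ndarray | None = None
    kcat: float | None = None
    V: np.ndarray | None = None
    K: np.ndarray | None = None

    def __post_init__(self):
        self.gene_copy_number = np.asarray(self.gene_copy_number, dtype=np.int64)
        if np.any(self.gene_copy_number <= 0):
            raise ValueError("gene copy numbers must be positive")
        n = len(self.labels)
        if not (len(self.anticodons) == len(self.amino_acids) == self.gene_copy_number.size == n):
            raise ValueError("tRNA table columns have inconsistent lengths")

    @property
    def n_species(self) -> int:
        return len(self.labels)

    @property
    def T_tot(self) -> int:
        if self.T is None:
            raise ValueError("tRNA totals not populated; run the parameterization first")
        return int(np.sum(self.T))

    def index_of(self, label: str) -> int:
        """0-based index of a species label."""
        return self.labels.index(label)


def load_trna_table(path) -> TRNASpeciesTable:
    """Load a tRNA species table (kinetic fields unpopulated).

    Requires unique consecutive ids 1..S and positive gene copy numbers.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["id", "label", "anticodon", "amino_acid", "gene_copy_number"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"tRNA table {path}: missing column {col!r}")
    ids = df["id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError(f"tRNA table {path}: duplicate species ids")
    order = np.argsort(ids)
    df = df.iloc[order]
    if not np.array_equal(df["id"].to_numpy(), np.arange(1, len(df) + 1)):
        raise ValueError(f"tRNA table {path}: ids must be consecutive 1..S")
    if (df["gene_copy_number"] <= 0).any():
        raise ValueError(f"tRNA table {path}: non-positive gene copy number")
    return TRNASpeciesTable(
        labels=df["label"].astype(str).tolist(),
        anticodons=df["anticodon"].astype(str).tolist(),
        amino_acids=df["amino_acid"].astype(str).tolist(),
        gene_copy_number=df["gene_copy_number"].to_numpy(),
    )


def load_codon_map(path) -> CodonMap:
    return CodonMap.from_tsv(path)


def packaged_path(name: str) -> Path:
    """Path of a packaged data file (tRNA table, codon map, fixtures)."""
    return Path(importlib.resources.files("ribotraffic").joinpath("data", name))


def load_packaged_trna_table() -> TRNASpeciesTable:
    """The packaged 41-species S. cerevisiae-like table (approximate gene
    copy numbers, alphabetical species labelling)."""
    return load_trna_table(packaged_path("trna_sc.tsv"))


def load_packaged_codon_map() -> CodonMap:
    """Packaged 61-codon map; each sense codon is assigned to the single
    tRNA species that decodes it (Watson-Crick match first, otherwise the
    standard wobble reader)."""
    return CodonMap.from_tsv(packaged_path("codon_map_sc.tsv"))


def read_orf_fasta(path, code: CodonMap, on_internal_stop: str = "error") -> list:
    """Read ORFs from FASTA and map them to tRNA-species id sequences.

    The terminal stop codon (if present) is trimmed before mapping; U and T
    are treated identically; record order is preserved.

    Parameters
    ----------
    on_internal_stop : "error" or "truncate"
        An internal stop codon either raises, or truncates the record at the
        first stop.
    """
    if on_internal_stop not in ("error", "truncate"):
        raise ValueError("on_internal_stop must be 'error' or 'truncate'")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _norm_codon(str(rec.seq))
        if len(seq) % 3 != 0:
            raise ValueError(
                f"record {rec.id!r}: length {len(seq)} not a multiple of 3"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        internal = [j for j, c in enumerate(codons) if c in STOP_CODONS]
        if internal:
            if on_internal_stop == "error":
                raise ValueError(
                    f"record {rec.id!r}: internal stop codon at codon {internal[0] + 1}"
                )
            codons = codons[: internal[0]]
        ids = np.empty(len(codons), dtype=np.int64)
        for j, c in enumerate(codons):
            if c not in code:
                raise ValueError(f"record {rec.id!r}: unmapped codon {c!r} at position {j + 1}")
            ids[j] = code[c]
        out.append(NamedCodonSequence(rec.id, ids))
    return out


# ---------------------------------------------------------------------------
# Results


def write_results(obs, ana=None, outdir=None) -> dict:
    """Write an ObservableSet (and optionally an AnalyticsResult) to a
    directory: one density-profile TSV per mRNA species, a charging-level
    TSV and a key-value summary.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in obs.mrna_names:
        prof = obs.profile_frame(name)
        p = outdir / f"profile_{name}.tsv"
        prof.to_csv(p, sep="\t", index=False, float_format="%.8g")
        paths[f"profile_{name}"] = p
    ch = obs.charging_frame()
    p = outdir / "charging.tsv"
    ch.to_csv(p, sep="\t", index=False, float_format="%.8g")
    paths["charging"] = p
    summ = obs.summary_dict()
    if ana is not None:
        summ.update(ana.summary_dict())
    p = outdir / "summary.tsv"
    with open(p, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in summ.items():
            fh.write(f"{k}\t{v:.10g}\n" if isinstance(v, float) else f"{k}\t{v}\n")
    paths["summary"] = p
    return paths


def read_results(outdir) -> dict:
    """Round-trip reader for :func:`write_results` output."""
    outdir = Path(outdir)
    out = {"profiles": {}, "charging": None, "summary": {}}
    for p in sorted(outdir.glob("profile_*.tsv")):
        out["profiles"][p.stem.removeprefix("profile_")] = pd.read_csv(p, sep="\t")
    ch = outdir / "charging.tsv"
    if ch.exists():
        out["charging"] = pd.read_csv(ch, sep="\t")
    summ = outdir / "summary.tsv"
    if summ.exists():
        df = pd.read_csv(summ, sep="\t")
        for k, v in zip(df["key"], df["value"]):
            try:
                out["summary"][k] = float(v)
            except (TypeError, ValueError):
                out["summary"][k] = v
    return out
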