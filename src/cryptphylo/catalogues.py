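"""Signature catalogues: named channel-probability vectors.

Reads and writes the COSMIC tab-separated layout (channel-label column
named ``Type`` followed by one column per signature).  Ships small
synthetic catalogues used by the cohort generator and the test suite;
real COSMIC tables can be loaded with :meth:`SignatureCatalogue.read`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import ID83_LABELS, SBS96_LABELS

__all__ = [
    "SignatureCatalogue",
    "synthetic_sbs_catalogue",
    "synthetic_id_catalogue",
    "random_catalogue",
]


@dataclass
class SignatureCatalogue:
    """Channels x signatures probability table (columns sum to 1)."""

    table: pd.DataFrame  # index = channel labels, columns = signature names

    def __post_init__(self) -> None:
        colsums = self.table.to_numpy(dtype=float).sum(axis=0)
        if (self.table.to_numpy() < 0).any():
            raise ValueError("signature vectors must be non-negative")
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1 within 1e-6")

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    @property
    def channels(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def matrix(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    def vector(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"unknown signature {name!r}")
        return self.table[name].to_numpy(dtype=float)

    def subset(self, names: list[str]) -> "SignatureCatalogue":
        missing = [n for n in names if n not in self.table.columns]
        if missing:
            raise KeyError(f"unknown signatures: {missing}")
        return SignatureCatalogue(self.table[names].copy())

    def with_signature(self, name: str, vector: np.ndarray) -> "SignatureCatalogue":
        t = self.table.copy()
        t[name] = np.asarray(vector, dtype=float)
        return SignatureCatalogue(t)

    # COSMIC-format I/O
    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "Type"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "SignatureCatalogue":
        table = pd.read_csv(path, sep="\t", index_col=0)
        return cls(table)


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / v.sum()


def _peaked(labels: list[str], peaks: dict[str, float], floor: float = 0.02) -> np.ndarray:
    """A vector with most mass on named channels plus a small flat floor."""
    v = np.full(len(labels), floor / len(labels))
    for lab, w in peaks.items():
        v[labels.index(lab)] += w
    return _normalize(v)


def synthetic_sbs_catalogue() -> SignatureCatalogue:
    """Four synthetic 96-channel signatures with pairwise cosine < 0.5.

    They caricature well-known processes (CpG deamination clock, flat
    age-related, MMR-deficiency-like, APOBEC-like) but are synthetic
    constructions, not COSMIC vectors.
    """
    labels = SBS96_LABELS
    clock = _peaked(labels, {f"{f}[C>T]G": 0.24 for f in "ACGT"})
    flat = np.ones(96)
    for i, lab in enumerate(labels):
        if "[T>C]" in lab:
            flat[i] = 2.0
    flat = _normalize(flat)
    mmr = _peaked(
        labels,
        {f"G[C>A]{t}": 0.12 for t in "ACGT"}
        | {f"C[T>A]{t}": 0.12 for t in "ACGT"},
    )
    apobec = _peaked(labels, {"T[C>G]A": 0.24, "T[C>G]T": 0.24,
                              "T[C>T]A": 0.24, "T[C>T]T": 0.24})
    table = pd.DataFrame(
        {"SIG_CLOCK": clock, "SIG_FLAT": flat, "SIG_MMR": mmr,
         "SIG_APOBEC": apobec},
        index=labels,
    )
    return SignatureCatalogue(table)


def synthetic_id_catalogue() -> SignatureCatalogue:
    """Four synthetic 83-channel indel signatures: T-insertion slippage
    (ID1-like), T-deletion slippage (ID2-like), polynucleotide repeat
    deletions (microsatellite-retraction-like), and microhomology
    deletions."""
    labels = ID83_LABELS
    slip_ins = _peaked(labels, {"1:Ins:T:4": 0.35, "1:Ins:T:5": 0.45,
                                "1:Ins:T:3": 0.15})
    slip_del = _peaked(labels, {"1:Del:T:4": 0.35, "1:Del:T:5": 0.45,
                                "1:Del:T:3": 0.15})
    ms_del = _peaked(
        labels,
        {f"{s}:Del:R:{n}": w
         for s, w in ((2, 0.06), (3, 0.06), (4, 0.06), (5, 0.06))
         for n in (3, 4, 5)},
    )
    mh_del = _peaked(labels, {"2:Del:M:1": 0.2, "3:Del:M:2": 0.2,
                              "4:Del:M:2": 0.2, "5:Del:M:3": 0.2,
                              "5:Del:M:5": 0.15})
    table = pd.DataFrame(
        {"ID_SLIP_INS": slip_ins, "ID_SLIP_DEL": slip_del,
         "ID_MS_DEL": ms_del, "ID_MH_DEL": mh_del},
        index=labels,
    )
    return SignatureCatalogue(table)


def random_catalogue(n_signatures: int, n_channels: int = 96,
                     concentration: float = 0.1, seed: int = 0,
                     max_pairwise_cosine: float = 0.3,
                     labels: list[str] | None = None) -> SignatureCatalogue:
    """Random sparse signatures with bounded pairwise cosine, for tests."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = SBS96_LABELS if n_channels == 96 else (
            ID83_LABELS if n_channels == 83 else
            [f"ch{i}" for i in range(n_channels)])
    sigs: list[np.ndarray] = []
    for _ in range(10_000):
        if len(sigs) == n_signatures:
            break
        v = rng.dirichlet(np.full(n_channels, concentration))
        ok = all(
            float(v @ s / (np.linalg.norm(v) * np.linalg.norm(s))) < max_pairwise_cosine
            for s in sigs
        )
        if ok:
            sigs.append(v)
    else:
        raise RuntimeError("could not draw sufficiently separated signatures")
    table = pd.DataFrame(
        np.column_stack(sigs), index=labels,
        columns=[f"RAND{i + 1}" for i in range(n_signatures)],
    )
    return SignatureCatalogue(table)
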