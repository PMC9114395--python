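"""The variants-by-samples read-count grid, the pipeline's substrate."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Per-patient variant x sample alt/total read counts.

    ``variants`` holds one row per site (id, chrom, pos, ref, alt, kind,
    context/flanks, annotations); ``samples`` one row per crypt (id,
    patient, tissue, crypt_type, age, optional ``cnv`` flag).  ``alt``
    and ``depth`` are integer arrays of shape (n_variants, n_samples).
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    alt: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        nv, ns = self.alt.shape
        if self.depth.shape != (nv, ns):
            raise ValueError("alt/depth shape mismatch")
        if len(self.variants) != nv or len(self.samples) != ns:
            raise ValueError("metadata does not match count dimensions")
        if (self.alt > self.depth).any():
            raise ValueError("alt exceeds depth")
        if (self.alt < 0).any() or (self.depth < 0).any():
            raise ValueError("negative counts")

    @property
    def n_variants(self) -> int:
        return self.alt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alt.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["id"])

    def vaf(self) -> np.ndarray:
        """Variant allele fractions; NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depth > 0, self.alt / self.depth, np.nan)

    def subset_variants(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return CountMatrix(
            self.variants.iloc[idx].reset_index(drop=True),
            self.samples,
            self.alt[idx],
            self.depth[idx],
        )

    # -- text round trip ---------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "cohort") -> None:
        """Write variants, samples, and an ``alt:depth`` cell grid as TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(outdir / f"{prefix}.variants.tsv", sep="\t", index=False)
        self.samples.to_csv(outdir / f"{prefix}.samples.tsv", sep="\t", index=False)
        cells = pd.DataFrame(
            np.char.add(
                np.char.add(self.alt.astype(str), ":"), self.depth.astype(str)
            ),
            index=self.variants["id"],
            columns=self.sample_ids,
        )
        cells.to_csv(outdir / f"{prefix}.counts.tsv", sep="\t")

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "cohort") -> "CountMatrix":
        outdir = Path(outdir)
        variants = pd.read_csv(outdir / f"{prefix}.variants.tsv", sep="\t")
        samples = pd.read_csv(outdir / f"{prefix}.samples.tsv", sep="\t")
        cells = pd.read_csv(outdir / f"{prefix}.counts.tsv", sep="\t", index_col=0)
        split = cells.to_numpy().astype(str)
        alt = np.vectorize(lambda s: int(s.split(":")[0]))(split)
        depth = np.vectorize(lambda s: int(s.split(":")[1]))(split)
        return cls(variants, samples, alt, depth)
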