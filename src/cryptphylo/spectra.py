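"""SBS96 and ID83 mutation channel classification and per-branch spectra.

Channel orders
--------------
SBS96: substitution class major (C>A, C>G, C>T, T>A, T>C, T>G), then 5'
flank, then 3' flank, each in A,C,G,T order: ``A[C>A]A, A[C>A]C, ...,
T[T>G]T``.  Substitutions are pyrimidine-normalized: a mutation reported
on the purine strand is reverse-complemented before classification.

ID83: COSMIC/PCAWG-style labels ``{len}:{Del|Ins}:{C|T|R|M}:{n}``.

* ``1:Del:{C,T}:n`` - 1-bp deletion in a homopolymer of the deleted base;
  ``n`` in 0..5 encodes total run length 1,2,3,4,5,6+ (the deleted copy
  counts, so ``0`` means the base had no equal neighbour).
* ``1:Ins:{C,T}:n`` - 1-bp insertion; ``n`` encodes the pre-existing run
  0,1,2,3,4,5+.
* ``{2,3,4,5}:Del:R:n`` - deletion of a 2/3/4/5+ bp motif at a tandem
  repeat; ``n`` encodes total repeat units 1..6+ (deleted copy counts).
* ``{2,3,4,5}:Ins:R:n`` - insertion of a motif; ``n`` = pre-existing
  units 0..5+.
* ``{2,3,4,5}:Del:M:m`` - deletion with microhomology of length ``m``
  (only when the motif has no full adjacent copy).

Repeats are counted on the 3' flank; indels are assumed left-aligned
upstream, so adjacent copies sit 3' of the event.  Microhomology is the
longest of (prefix of the deleted motif at the start of the 3' flank,
suffix of the deleted motif at the end of the 5' flank).

Indel variants are represented with ``ref`` = deleted sequence and
``alt`` = ``"-"`` for deletions, and ``ref`` = ``"-"``, ``alt`` =
inserted sequence for insertions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SBS96_LABELS",
    "ID83_LABELS",
    "sbs_channel",
    "id_channel",
    "repeat_units",
    "microsatellite_frameshift_flag",
    "branch_spectra",
    "spectrum_from_variants",
]

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

SBS96_LABELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_SBS96_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def _id83_labels() -> list[str]:
    labels = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{n}" for n in range(6)]
    for size in (2, 3, 4, 5):
        labels += [f"{size}:Del:R:{n}" for n in range(6)]
    for size in (2, 3, 4, 5):
        labels += [f"{size}:Ins:R:{n}" for n in range(6)]
    mh = {2: [1], 3: [1, 2], 4: [1, 2, 3], 5: [1, 2, 3, 4, 5]}
    for size, lens in mh.items():
        labels += [f"{size}:Del:M:{m}" for m in lens]
    return labels


ID83_LABELS = _id83_labels()
_ID83_INDEX = {lab: i for i, lab in enumerate(ID83_LABELS)}


def revcomp(seq: str) -> str:
    try:
        return "".join(_COMP[b] for b in reversed(seq))
    except KeyError as e:
        raise ValueError(f"non-ACGT base in {seq!r}") from e


def sbs_channel(ref: str, alt: str, context: str) -> int:
    """Classify a single-base substitution into one of the 96 channels.

    ``context`` is an odd-length window centered on the mutated base and
    must agree with ``ref`` at its center.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("sbs_channel expects single-base ref and alt")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if len(context) < 3 or len(context) % 2 != 1:
        raise ValueError("context must be odd-length and >= 3")
    mid = len(context) // 2
    if context[mid] != ref:
        raise ValueError("context center does not match ref")
    if ref in "AG":  # pyrimidine strand normalization
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
        mid = len(context) // 2
    label = f"{context[mid - 1]}[{ref}>{alt}]{context[mid + 1]}"
    try:
        return _SBS96_INDEX[label]
    except KeyError as e:
        raise ValueError(f"cannot classify {label}") from e


def repeat_units(motif: str, flank_3prime: str) -> int:
    """Number of consecutive full copies of ``motif`` at the start of the
    3' flank.  Adjacency is required; partial copies do not count."""
    if not motif:
        raise ValueError("empty motif")
    n = 0
    pos = 0
    L = len(motif)
    while flank_3prime[pos:pos + L] == motif:
        n += 1
        pos += L
    return n


def _suffix_units(motif: str, flank_5prime: str) -> int:
    """Adjacent full copies of ``motif`` at the end of the 5' flank."""
    n = 0
    L = len(motif)
    pos = len(flank_5prime)
    while pos >= L and flank_5prime[pos - L:pos] == motif:
        n += 1
        pos -= L
    return n


def _microhomology(motif: str, lflank: str, rflank: str) -> int:
    """Longest prefix of ``motif`` at the start of the 3' flank or suffix
    of ``motif`` at the end of the 5' flank (proper: < len(motif))."""
    best = 0
    for m in range(len(motif) - 1, 0, -1):
        if rflank.startswith(motif[:m]) or lflank.endswith(motif[-m:]):
            best = m
            break
    return best


def id_channel(ref: str, alt: str, lflank: str, rflank: str) -> int:
    """Classify an insertion or deletion into one of the 83 channels."""
    if ref == "-" and alt != "-":
        motif, is_del = alt, False
    elif alt == "-" and ref != "-":
        motif, is_del = ref, True
    else:
        raise ValueError("indel must have ref='-' (ins) or alt='-' (del)")
    if any(b not in _COMP for b in motif):
        raise ValueError(f"non-ACGT base in {motif!r}")
    L = len(motif)
    min_flank = 6 * L
    if len(rflank) < min_flank or len(lflank) < min_flank:
        raise ValueError("flanks too short to count repeat units")

    if L == 1:
        # homopolymer runs are counted over both flanks: a purine-strand
        # event carries its run 5' after normalization, so one-sided
        # counting would break strand invariance
        base = motif
        units = repeat_units(base, rflank) + _suffix_units(base, lflank)
        label_base = _COMP[base] if base in "AG" else base
        if is_del:
            run = 1 + units           # deleted copy counts
            n = min(run, 6) - 1
            return _ID83_INDEX[f"1:Del:{label_base}:{n}"]
        n = min(units, 5)
        return _ID83_INDEX[f"1:Ins:{label_base}:{n}"]

    size = min(L, 5)
    units3 = repeat_units(motif, rflank)
    if not is_del:
        n = min(units3, 5)
        return _ID83_INDEX[f"{size}:Ins:R:{n}"]
    total_units = 1 + units3
    if total_units == 1:
        mh = _microhomology(motif, lflank, rflank)
        if mh >= 1:
            mh = min(mh, 5)
            return _ID83_INDEX[f"{size}:Del:M:{mh}"]
    n = min(total_units, 6) - 1
    return _ID83_INDEX[f"{size}:Del:R:{n}"]


def microsatellite_frameshift_flag(ref: str, alt: str, lflank: str,
                                   rflank: str) -> bool:
    """True when the indel sits in a repeat tract of >= 5 units (run
    length >= 5 for homopolymers), the criterion used to mark
    microsatellite frameshift events among drivers."""
    if ref == "-" and alt != "-":
        motif, is_del = alt, False
    elif alt == "-" and ref != "-":
        motif, is_del = ref, True
    else:
        raise ValueError("not an indel")
    units = repeat_units(motif, rflank) + _suffix_units(motif, lflank)
    if is_del:
        units += 1
    return units >= 5


def spectrum_from_variants(variants: pd.DataFrame, kind: str = "SBS") -> np.ndarray:
    """Count channels over a variant table (columns per :mod:`.simdata`)."""
    if kind == "SBS":
        n = len(SBS96_LABELS)
        rows = variants[variants["kind"] == "SBS"]
        idx = [sbs_channel(r.ref, r.alt, r.context) for r in rows.itertuples()]
    else:
        n = len(ID83_LABELS)
        rows = variants[variants["kind"].isin(["INS", "DEL"])]
        idx = [id_channel(r.ref, r.alt, r.lflank, r.rflank) for r in rows.itertuples()]
    return np.bincount(np.asarray(idx, dtype=int), minlength=n).astype(float)


def branch_spectra(
    assignments: pd.DataFrame,
    variants: pd.DataFrame,
    kind: str = "SBS",
    min_mutations: int = 100,
    cap: int = 2500,
    seed: int = 0,
    patient_of_branch: dict | None = None,
) -> pd.DataFrame:
    """Per-branch channel-count matrix with the inclusion and cap rules.

    ``assignments`` needs columns ``variant`` and ``branch``.  Branches
    with fewer than ``min_mutations`` assigned variants are excluded;
    branches above ``cap`` are randomly subsampled to exactly ``cap``
    (seeded), which preserves the branch spectrum in expectation.

    Returns a DataFrame (rows = branch labels, columns = channel labels)
    with a ``patient`` column prepended when a hierarchy map is given.
    """
    rng = np.random.default_rng(seed)
    labels = SBS96_LABELS if kind == "SBS" else ID83_LABELS
    var = variants.set_index("id")
    rows = {}
    for branch, grp in assignments.groupby("branch", sort=True):
        ids = grp["variant"].to_numpy()
        if len(ids) < min_mutations:
            continue
        if len(ids) > cap:
            ids = rng.choice(ids, size=cap, replace=False)
        sub = var.loc[ids].reset_index()
        rows[branch] = spectrum_from_variants(sub, kind=kind)
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    mat.index.name = "branch"
    if patient_of_branch is not None:
        mat.insert(0, "patient", [patient_of_branch[b] for b in mat.index])
    return mat
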