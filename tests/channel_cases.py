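"""Hand-constructed SBS and indel classification cases.

Each SBS case is (ref, alt, context, expected label); each indel case
is (ref, alt, 5' flank, 3' flank, expected label).  Expected labels
were derived by hand from the channel definitions (pyrimidine strand
normalization; homopolymer runs counted over both flanks for 1-bp
events; 3'-anchored repeat units for longer motifs; microhomology as
the longest flank-matching prefix/suffix of the deleted motif).
"""

# filler sequences that cannot extend any motif used below
_L = "ACGACGACGACGACGACGACGACGACGACGACGACGACGACGACG"  # ends ...ACG


def L(end: str = "") -> str:
    """A 45-bp left flank ending in the given sequence."""
    if not end:
        return _L
    return _L[: len(_L) - len(end)] + end


def R(start: str = "", filler: str = "GTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTCGTC") -> str:
    """A 45-bp right flank starting with the given sequence."""
    return (start + filler)[:45]


SBS_CASES = [
    # direct pyrimidine representations
    ("C", "T", "ACG", "A[C>T]G"),
    ("C", "A", "ACA", "A[C>A]A"),
    ("C", "G", "TCT", "T[C>G]T"),
    ("C", "T", "GCC", "G[C>T]C"),
    ("C", "A", "CCG", "C[C>A]G"),
    ("T", "A", "GTC", "G[T>A]C"),
    ("T", "C", "ATG", "A[T>C]G"),
    ("T", "G", "CTT", "C[T>G]T"),
    ("T", "C", "TTT", "T[T>C]T"),
    ("T", "A", "ATA", "A[T>A]A"),
    ("C", "G", "GCA", "G[C>G]A"),
    ("T", "G", "GTG", "G[T>G]G"),
    # purine-strand representations (reverse complement before lookup)
    ("G", "A", "TGC", "G[C>T]A"),      # revcomp(TGC) = GCA
    ("G", "T", "CGG", "C[C>A]G"),      # revcomp(CGG) = CCG
    ("G", "C", "GGA", "T[C>G]C"),      # revcomp(GGA) = TCC
    ("A", "G", "CAT", "A[T>C]G"),      # revcomp(CAT) = ATG
    ("A", "T", "TAA", "T[T>A]A"),      # revcomp(TAA) = TTA
    ("A", "C", "GAG", "C[T>G]C"),      # revcomp(GAG) = CTC
    ("G", "A", "GGG", "C[C>T]C"),
    ("A", "G", "AAA", "T[T>C]T"),
    ("G", "T", "TGT", "A[C>A]A"),
    ("A", "C", "CAC", "G[T>G]G"),
    ("G", "C", "AGC", "G[C>G]T"),      # revcomp(AGC) = GCT
    ("A", "T", "GAC", "G[T>A]C"),      # revcomp(GAC) = GTC
    # wider context windows (5-mers); only immediate flanks matter
    ("C", "T", "AACGT", "A[C>T]G"),
    ("T", "G", "CGTAC", "G[T>G]A"),
    ("G", "A", "ATGCA", "G[C>T]A"),    # revcomp(ATGCA) = TGCAT
    ("A", "C", "TTACC", "G[T>G]A"),    # revcomp(TTACC) = GGTAA
    ("C", "A", "TGCAT", "G[C>A]A"),
    ("T", "C", "CATGC", "A[T>C]G"),
]

ID_CASES = [
    # 1-bp deletions in homopolymers (run includes the deleted base)
    ("T", "-", L(), R("TTTTT"), "1:Del:T:5"),              # run 6
    ("T", "-", L(), R("TTT"), "1:Del:T:3"),                # run 4
    ("C", "-", L(), R(), "1:Del:C:0"),                     # lone C
    ("C", "-", L("CC"), R("C"), "1:Del:C:3"),              # run 2+1+1 = 4
    ("T", "-", L(), R("TTTTTTTTT"), "1:Del:T:5"),          # run 10 -> 6+
    ("A", "-", L("AAAA"), R(), "1:Del:T:4"),               # A run 5 -> T strand
    ("G", "-", L("GG"), R("GT"), "1:Del:C:3"),             # G run 4 -> C strand
    # 1-bp insertions (pre-existing run)
    ("-", "C", L(), R("CCC"), "1:Ins:C:3"),
    ("-", "T", L(), R(), "1:Ins:T:0"),
    ("-", "T", L("TT"), R("TT"), "1:Ins:T:4"),
    ("-", "C", L(), R("CCCCCCC"), "1:Ins:C:5"),            # run 7 -> 5+
    ("-", "A", L(), R("AAAA"), "1:Ins:T:4"),               # A -> T strand
    ("-", "G", L("GGGGG"), R(), "1:Ins:C:5"),              # 5' G run 5
    # multi-bp deletions at tandem repeats (units include deleted copy)
    ("CA", "-", L(), R("CACA"), "2:Del:R:2"),              # 3 units
    ("AT", "-", L(), R("GTC"), "2:Del:R:0"),               # 1 unit, no MH
    ("TA", "-", L(), R("TATATG"), "2:Del:R:2"),            # 3 units
    ("AT", "-", L(), R("ATATATATATAT"), "2:Del:R:5"),      # 7 units -> 6+
    ("CTG", "-", L(), R("CTGCTG"), "3:Del:R:2"),           # 3 units
    ("CCCC", "-", L(), R("GTC"), "4:Del:R:0"),             # no copy, no MH
    ("ACGTA", "-", L(), R("ACGTAACGTA"), "5:Del:R:2"),     # 3 units
    ("CACACA", "-", L(), R("GTC"), "5:Del:R:0"),           # 6-bp motif
    # multi-bp insertions
    ("-", "CA", L(), R("CACA"), "2:Ins:R:2"),
    ("-", "GG", L(), R("GGGG"), "2:Ins:R:2"),
    ("-", "GGC", L(), R("GGCGGCGGCGGCGGCGGC"), "3:Ins:R:5"),  # 6 -> 5+
    ("-", "ACGT", L(), R("ACGT"), "4:Ins:R:1"),
    ("-", "TTAGG", L(), R("GTC"), "5:Ins:R:0"),
    # deletions with microhomology (no full adjacent copy)
    ("TG", "-", L(), R("TC"), "2:Del:M:1"),
    ("GAC", "-", L(), R("GTT"), "3:Del:M:1"),
    ("TAGC", "-", L(), R("TAT"), "4:Del:M:2"),
    ("AGGC", "-", L("GC"), R("GTC"), "4:Del:M:2"),         # 5' suffix MH
    ("ACGTA", "-", L(), R("ACGAC"), "5:Del:M:3"),
    ("GATTACA", "-", L(), R("GATTC"), "5:Del:M:4"),
]
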