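"""Shared low-level helpers: base/k-mer integer coding, genome container, smoothing.

Bases are coded A=0, C=1, G=2, T=3; anything else (N, IUPAC ambiguity) is -1.
A k-mer is coded as a base-4 integer with the first base in the highest digit,
so "ACGT" -> 0*64 + 1*16 + 2*4 + 3 = 27.  K-mers touching an ambiguous base
code to -1 and are skipped by all counting routines.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as an int8 array (A=0,C=1,G=2,T=3, other=-1)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    out = np.full(len(codes), ord("N"), dtype=np.uint8)
    ok = codes >= 0
    out[ok] = _DECODE[codes[ok]]
    return out.tobytes().decode()


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Code of the k-mer starting at every position (length len(codes)-k+1).

    Positions whose k-mer contains an ambiguous base code to -1.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        out = out * 4 + np.where(c < 0, 0, c).astype(np.int64)
        bad |= c < 0
    out[bad] = -1
    return out


def revcomp_table(k: int) -> np.ndarray:
    """Lookup table mapping each k-mer code to its reverse complement's code."""
    n = 4**k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    for _ in range(k):
        rc = rc * 4 + (3 - codes % 4)
        codes //= 4
    return rc


class Genome:
    """In-memory genome: chromosome name -> int8 base-code array.

    Built from a FASTA file (via pyfaidx) or from plain strings; caches the
    per-position k-mer code arrays that the bias and profile modules gather
    from repeatedly.
    """

    def __init__(self, codes: dict[str, np.ndarray]):
        self._codes = codes
        self._kmers: dict[tuple[str, int], np.ndarray] = {}

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Genome":
        return cls({c: seq_to_codes(s) for c, s in seqs.items()})

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: seq_to_codes(str(fa[name][:])) for name in fa.keys()})

    @property
    def chroms(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._codes.items()}

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def seq(self, chrom: str, start: int, end: int) -> str:
        return codes_to_seq(self._codes[chrom][start:end])

    def kmers(self, chrom: str, k: int) -> np.ndarray:
        key = (chrom, k)
        if key not in self._kmers:
            self._kmers[key] = kmer_codes(self._codes[chrom], k)
        return self._kmers[key]

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, codes in self._codes.items():
                fh.write(f">{chrom}\n")
                s = codes_to_seq(codes)
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


def sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; `window` is forced odd (window//2 each side)."""
    w = window if window % 2 == 1 else window + 1
    kern = np.ones(w) / w
    return np.convolve(np.asarray(x, dtype=float), kern, mode="same")


def rng_from_seed(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
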