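"""Degenerate peptide windows and per-protein peptide pools.

A protein sequence is reduced to a *peptide pool*: every length-``N`` window
is expanded into all C(N, A) variant strings obtained by replacing exactly
``A`` positions with the wildcard ``X``.  Two windows then "share" a peptide
exactly when their Hamming distance is at most ``A``, so approximate window
matching reduces to exact string equality of variants — the trick that makes
the whole pipeline dictionary-lookup fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

WILDCARD = "X"

#: The 20 standard amino-acid one-letter codes. ``X`` is reserved for the
#: wildcard, so an ``X`` occurring in input data is treated as nonstandard
#: and the windows containing it are skipped — wildcards can never collide
#: with data.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideParams:
    """Window length ``n`` and number of ambiguous positions ``a``.

    The defaults (8 residues, 2 wildcards) are the parameters found to give
    the best precision/sensitivity trade-off for CAZy family clustering.
    """

    n: int = 8
    a: int = 2

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"window length must be >= 2, got {self.n}")
        if not 0 <= self.a < self.n:
            raise ValueError(
                f"ambiguous count must satisfy 0 <= a < n, got a={self.a}, n={self.n}"
            )

    @property
    def variants_per_window(self) -> int:
        return comb(self.n, self.a)

    def __str__(self) -> str:  # "8x2" notation
        return f"{self.n}x{self.a}"

    @classmethod
    def parse(cls, text: str) -> "PeptideParams":
        """Parse the ``"8x2"`` notation used on the command line."""
        try:
            n_str, a_str = text.lower().split("x")
            return cls(int(n_str), int(a_str))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse peptide parameters from {text!r}") from exc


@dataclass
class PeptidePool:
    """Bag-of-peptides representation of one protein.

    ``entries`` maps each variant string to the set of 0-based window start
    positions at which it occurs.  Start positions use half-open
    ``[s, s + n)`` residue coordinates.
    """

    protein_id: str
    sequence_length: int
    entries: dict[str, set[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def peptides(self) -> set[str]:
        return set(self.entries)

    def all_starts(self) -> set[int]:
        """Distinct window start positions of every peptide in the pool."""
        out: set[int] = set()
        for starts in self.entries.values():
            out.update(starts)
        return out

    def covered_positions(self, n: int) -> set[int]:
        """Residue indices covered by at least one peptide window."""
        out: set[int] = set()
        for s in self.all_starts():
            out.update(range(s, s + n))
        return out


def expand_variants(window: str, a: int) -> set[str]:
    """Expand a clean window into all C(n, a) wildcard variants.

    Parameters
    ----------
    window
        A string over the 20 standard residues; its length defines ``n``.
    a
        Number of positions replaced by the wildcard, ``0 <= a < n``.

    Returns
    -------
    set of str
        Exactly C(n, a) distinct strings, one per ``a``-subset of positions.
    """
    n = len(window)
    if not 0 <= a < n:
        raise ValueError(f"ambiguous count must satisfy 0 <= a < n, got a={a}, n={n}")
    bad = set(window) - STANDARD_RESIDUES
    if bad:
        raise ValueError(
            f"window {window!r} contains nonstandard residues {sorted(bad)}; "
            f"only the 20 standard amino acids are allowed (X is the wildcard)"
        )
    if a == 0:
        return {window}
    variants: set[str] = set()
    chars = list(window)
    for positions in combinations(range(n), a):
        v = chars.copy()
        for p in positions:
            v[p] = WILDCARD
        variants.add("".join(v))
    return variants


def window_is_clean(window: str) -> bool:
    """True when every character is one of the 20 standard residues."""
    return not (set(window) - STANDARD_RESIDUES)


def build_pool(
    protein_id: str, sequence: str, params: PeptideParams
) -> PeptidePool:
    """Slide a window across ``sequence`` and collect all peptide variants.

    Windows containing nonstandard characters (``X``, ``B``, ``Z``, ``J``,
    ``U``, ``O``, ``*``, gaps, ...) contribute nothing; only the offending
    windows are skipped, not the whole protein.  A sequence shorter than the
    window yields an empty pool with a warning rather than an error.
    """
    seq = sequence.upper()
    pool = PeptidePool(protein_id=protein_id, sequence_length=len(seq))
    n, a = params.n, params.a
    if len(seq) < n:
        warnings.warn(
            f"sequence {protein_id!r} shorter than window ({len(seq)} < {n}); "
            f"empty peptide pool",
            stacklevel=2,
        )
        return pool
    # Precompute cleanliness per residue, then per window via a running count.
    ok = [c in STANDARD_RESIDUES for c in seq]
    bad_in_window = sum(not v for v in ok[:n])
    for s in range(len(seq) - n + 1):
        if s > 0:
            bad_in_window += (not ok[s + n - 1]) - (not ok[s - 1])
        if bad_in_window:
            continue
        for variant in expand_variants(seq[s : s + n], a):
            pool.entries.setdefault(variant, set()).add(s)
    return pool


def build_pools(
    sequences: dict[str, str], params: PeptideParams
) -> dict[str, PeptidePool]:
    """Build a pool per protein, keyed and ordered by protein id."""
    return {
        pid: build_pool(pid, sequences[pid], params) for pid in sorted(sequences)
    }


def hamming(u: str, v: str) -> int:
    if len(u) != len(v):
        raise ValueError("windows must have equal length")
    return sum(x != y for x, y in zip(u, v))


def windows_share_variant(u: str, v: str, a: int) -> bool:
    """True iff windows ``u`` and ``v`` share at least one wildcard variant.

    Equivalent to ``hamming(u, v) <= a``: a shared variant must place
    wildcards on every mismatching position, which is possible exactly when
    there are at most ``a`` mismatches.
    """
    return hamming(u, v) <= a
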