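"""Exhaustive enumeration of cleavage and splice products of a substrate.

A cleavage product (PCP) is a contiguous substring of the substrate,
addressed by 1-based inclusive coordinates (i, j).  A splice product (PSP)
is the head-to-tail ligation of an ordered pair of cleavage products,
addressed by the quadruple (i, j, k, n).  Splice products fall into three
classes:

* ``cis_normal``  — same substrate molecule, second fragment strictly
  downstream with a gap of at least one residue (k >= j + 2);
* ``cis_reverse`` — same substrate molecule, second fragment entirely
  upstream (i >= n + 1, zero gap allowed);
* ``trans``       — everything else: overlapping fragments, a fragment
  paired with itself, or fragments from two distinct substrate molecules.

Ordered pairs with k = j + 1 on the same substrate reconstitute a native
contiguous sequence (indistinguishable from a cleavage product) and are
excluded from enumeration by default.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .masses import CANONICAL_RESIDUES

__all__ = [
    "Substrate",
    "FragmentIndex",
    "SpliceIndex",
    "PspClass",
    "EnumerationParams",
    "ProductCounts",
    "enumerate_pcp",
    "classify",
    "enumerate_psp",
    "count_products",
    "sequence_of",
]


class PspClass(enum.Enum):
    CIS_NORMAL = "cis_normal"
    CIS_REVERSE = "cis_reverse"
    TRANS = "trans"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


ALL_CLASSES = frozenset(PspClass)


@dataclass(frozen=True)
class Substrate:
    """A polypeptide substrate with optional per-position isotope labels."""

    id: str
    sequence: str
    label_offsets: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"substrate {self.id!r}: length must be >= 2")
        bad = set(self.sequence) - set(CANONICAL_RESIDUES)
        if bad:
            raise ValueError(f"substrate {self.id!r}: non-canonical residues {sorted(bad)}")
        if self.label_offsets:
            for pos in self.label_offsets:
                if not 1 <= pos <= len(self.sequence):
                    raise ValueError(f"substrate {self.id!r}: label position {pos} out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    def fragment(self, i: int, j: int) -> str:
        return self.sequence[i - 1 : j]


@dataclass(frozen=True, order=True)
class FragmentIndex:
    """1-based inclusive coordinates of a cleavage product."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not 1 <= self.i <= self.j:
            raise ValueError(f"invalid fragment index ({self.i},{self.j})")

    @property
    def length(self) -> int:
        return self.j - self.i + 1


@dataclass(frozen=True)
class SpliceIndex:
    """An ordered pair of fragments: first is ligated N-terminally of second."""

    first: FragmentIndex
    second: FragmentIndex
    substrate_first: Substrate
    substrate_second: Substrate

    def __post_init__(self) -> None:
        for frag, sub in ((self.first, self.substrate_first), (self.second, self.substrate_second)):
            if frag.j > len(sub):
                raise ValueError(f"fragment {frag} exceeds substrate {sub.id!r} of length {len(sub)}")

    @property
    def same_substrate(self) -> bool:
        return self.substrate_first is self.substrate_second or (
            self.substrate_first.id == self.substrate_second.id
        )

    @property
    def ijkn(self) -> tuple[int, int, int, int]:
        return (self.first.i, self.first.j, self.second.i, self.second.j)


@dataclass(frozen=True)
class EnumerationParams:
    l_ext: int = 2
    classes: frozenset[PspClass] = ALL_CLASSES
    include_native_adjacent: bool = False
    allow_self_pairing: bool = True

    def __post_init__(self) -> None:
        if self.l_ext < 1:
            raise ValueError("l_ext must be >= 1")
        if not self.classes:
            raise ValueError("classes must be non-empty")


@dataclass(frozen=True)
class ProductCounts:
    n_pcp: int
    n_cis_normal: int
    n_cis_reverse: int
    n_trans: int
    n_all_pairs: int
    n_native_adjacent: int = 0

    @property
    def n_psp(self) -> int:
        return self.n_cis_normal + self.n_cis_reverse + self.n_trans


def enumerate_pcp(substrate: Substrate, params: EnumerationParams | None = None) -> list[FragmentIndex]:
    """All (i, j) with length >= l_ext, in lexicographic order."""
    params = params or EnumerationParams()
    L = len(substrate)
    if params.l_ext > L:
        warnings.warn(
            f"l_ext={params.l_ext} exceeds substrate length {L}; no cleavage products",
            stacklevel=2,
        )
        return []
    return [
        FragmentIndex(i, j)
        for i in range(1, L - params.l_ext + 2)
        for j in range(i + params.l_ext - 1, L + 1)
    ]


def classify(idx: SpliceIndex) -> PspClass:
    """Assign the unique splice class of an ordered fragment pair.

    Native-adjacent pairs (k = j + 1, same substrate) classify as
    cis_normal; whether they are emitted at all is an enumeration concern.
    """
    if not idx.same_substrate:
        return PspClass.TRANS
    i, j, k, n = idx.ijkn
    if k >= j + 1:
        return PspClass.CIS_NORMAL
    if i >= n + 1:
        return PspClass.CIS_REVERSE
    return PspClass.TRANS


def enumerate_psp(
    substrates: Substrate | Sequence[Substrate],
    params: EnumerationParams | None = None,
    cross_only: bool = False,
) -> Iterator[tuple[SpliceIndex, PspClass]]:
    """Stream all qualifying ordered fragment pairs with their class.

    With one substrate, pairs are emitted in lexicographic (i, j, k, n)
    order.  With two substrates all four molecule pairings are covered
    (or only the two cross-molecule pairings if ``cross_only``); every
    cross-molecule pair is trans by definition.
    """
    params = params or EnumerationParams()
    if isinstance(substrates, Substrate):
        subs = [substrates]
    else:
        subs = list(substrates)
    if not 1 <= len(subs) <= 2:
        raise ValueError("enumerate_psp takes one or two substrates")
    if cross_only and len(subs) != 2:
        raise ValueError("cross_only requires two substrates")
    if len(subs) == 2 and subs[0].id == subs[1].id:
        raise ValueError("two substrates must have distinct ids")

    frags = {s.id: enumerate_pcp(s, params) for s in subs}
    if len(subs) == 1:
        pairings = [(subs[0], subs[0])]
    elif cross_only:
        pairings = [(subs[0], subs[1]), (subs[1], subs[0])]
    else:
        pairings = [
            (subs[0], subs[0]), (subs[0], subs[1]),
            (subs[1], subs[0]), (subs[1], subs[1]),
        ]

    for s1, s2 in pairings:
        same = s1.id == s2.id
        for f1 in frags[s1.id]:
            for f2 in frags[s2.id]:
                if same:
                    if f2.i == f1.j + 1 and not params.include_native_adjacent:
                        continue
                    if f1 == f2 and not params.allow_self_pairing:
                        continue
                idx = SpliceIndex(f1, f2, s1, s2)
                cls = classify(idx)
                if cls in params.classes:
                    yield idx, cls


def _tri(m: int) -> int:
    return m * (m + 1) // 2 if m > 0 else 0


def count_products(L: int, l_ext: int) -> ProductCounts:
    """Closed-form product counts for a single substrate of length L.

    Uses triangular-number identities rather than pair enumeration, so it
    serves as an independent cross-check of :func:`enumerate_psp`.
    Native-adjacent pairs (k = j + 1) are counted separately, matching the
    default enumeration behaviour.
    """
    if l_ext < 1:
        raise ValueError("l_ext must be >= 1")
    if L < l_ext:
        return ProductCounts(0, 0, 0, 0, 0, 0)
    n_pcp = _tri(L - l_ext + 1)
    # cis_normal: first fragment ends at j, second starts at k >= j + 2.
    cn = sum((j - l_ext + 1) * _tri(L - l_ext - j) for j in range(l_ext, L + 1))
    # cis_reverse: second fragment ends at n, first starts at i >= n + 1.
    cr = sum((n - l_ext + 1) * _tri(L - l_ext + 1 - n) for n in range(l_ext, L + 1))
    # native-adjacent: k = j + 1 exactly.
    adj = sum(
        (j - l_ext + 1) * (L - l_ext + 1 - j)
        for j in range(l_ext, L - l_ext + 1)
    )
    n_all = n_pcp * n_pcp
    n_trans = n_all - cn - cr - adj
    return ProductCounts(n_pcp, cn, cr, n_trans, n_all, adj)


def sequence_of(idx: FragmentIndex | SpliceIndex, substrate: Substrate | None = None) -> str:
    """Peptide string addressed by a fragment or splice index."""
    if isinstance(idx, FragmentIndex):
        if substrate is None:
            raise ValueError("sequence_of(FragmentIndex) needs a substrate")
        return substrate.fragment(idx.i, idx.j)
    return idx.substrate_first.fragment(idx.first.i, idx.first.j) + idx.substrate_second.fragment(
        idx.second.i, idx.second.j
    )


def label_deltas_of(idx: SpliceIndex) -> dict[int, float]:
    """Label offsets of a spliced product, re-indexed to the product sequence."""
    out: dict[int, float] = {}
    off1 = idx.substrate_first.label_offsets or {}
    off2 = idx.substrate_second.label_offsets or {}
    for pos, d in off1.items():
        if idx.first.i <= pos <= idx.first.j:
            out[pos - idx.first.i + 1] = d
    shift = idx.first.length
    for pos, d in off2.items():
        if idx.second.i <= pos <= idx.second.j:
            out[shift + pos - idx.second.i + 1] = d
    return out
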