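"""Theoretical product database: masses, per-charge m/z and m/z clustering.

Every enumerated cleavage (PCP) and splice (PSP) product becomes one
entry carrying its neutral mass and m/z at each configured charge state.
Because distinct products can differ by less than instrument accuracy,
the (entry, charge) m/z values are grouped into clusters of span at most
``cluster_width`` (default 0.2 Da) and each cluster is represented by the
arithmetic mean of its members; downstream screening operates on cluster
representatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import masses as m
from .enumeration import (
    EnumerationParams,
    FragmentIndex,
    ProductCounts,
    PspClass,
    SpliceIndex,
    Substrate,
    count_products,
    enumerate_pcp,
    enumerate_psp,
    label_deltas_of,
    sequence_of,
)

MAX_SUBSTRATE_LENGTH = 60  # combinatorial growth guardrail; override explicitly


@dataclass(frozen=True)
class DbParams:
    charges: tuple[int, ...] = (1, 2, 3)
    cluster_width: float = 0.2
    mass_mode: str = "mono"
    enumeration: EnumerationParams = field(default_factory=EnumerationParams)
    include_pcp_in_clusters: bool = False
    allow_long_substrates: bool = False

    def __post_init__(self) -> None:
        if not self.charges:
            raise ValueError("charge set must be non-empty")
        if any(z < 1 for z in self.charges):
            raise ValueError("charges must be >= 1")
        if self.cluster_width <= 0:
            raise ValueError("cluster_width must be positive")


@dataclass(frozen=True)
class TheoreticalEntry:
    kind: str                      # "PCP" | "PSP"
    substrate_first: str
    substrate_second: str | None
    i: int
    j: int
    k: int | None
    n: int | None
    sequence: str
    mr: float
    mz: dict[int, float]
    psp_class: PspClass | None

    @property
    def index_label(self) -> str:
        if self.kind == "PCP":
            return f"{self.i}-{self.j}"
        return f"{self.i}-{self.j}/{self.k}-{self.n}"


@dataclass
class MzCluster:
    cluster_id: int
    members: list[tuple[int, int]]      # (entry index, charge)
    mz_values: list[float]

    @property
    def representative(self) -> float:
        mean = math.fsum(self.mz_values) / len(self.mz_values)
        return min(max(mean, min(self.mz_values)), max(self.mz_values))

    @property
    def span(self) -> float:
        return max(self.mz_values) - min(self.mz_values)


@dataclass
class TheoreticalDatabase:
    entries: list[TheoreticalEntry]
    clusters: list[MzCluster]
    params: DbParams
    substrate_ids: tuple[str, ...]

    @property
    def psp_entries(self) -> list[TheoreticalEntry]:
        return [e for e in self.entries if e.kind == "PSP"]

    @property
    def pcp_entries(self) -> list[TheoreticalEntry]:
        return [e for e in self.entries if e.kind == "PCP"]


def cluster_mz(values: Sequence[float], width: float) -> list[list[int]]:
    """Greedy left-to-right span-bounded grouping over sorted values.

    Returns index groups into the *sorted* order of ``values``; a new group
    starts whenever adding the next value would stretch the group span
    beyond ``width``.
    """
    if width <= 0:
        raise ValueError("cluster width must be positive")
    order = sorted(range(len(values)), key=lambda ix: values[ix])
    groups: list[list[int]] = []
    current: list[int] = []
    lo = 0.0
    for ix in order:
        v = values[ix]
        if not current:
            current, lo = [ix], v
        elif v - lo <= width:
            current.append(ix)
        else:
            groups.append(current)
            current, lo = [ix], v
    if current:
        groups.append(current)
    return groups


def build_database(
    substrates: Substrate | Sequence[Substrate],
    params: DbParams | None = None,
    cross_only: bool = False,
) -> TheoreticalDatabase:
    """Enumerate all products of the substrate(s) and cluster their m/z."""
    params = params or DbParams()
    subs = [substrates] if isinstance(substrates, Substrate) else list(substrates)
    for s in subs:
        if len(s) > MAX_SUBSTRATE_LENGTH and not params.allow_long_substrates:
            raise ValueError(
                f"substrate {s.id!r} has length {len(s)} > {MAX_SUBSTRATE_LENGTH}; "
                "the product space grows combinatorially — pass "
                "allow_long_substrates=True to override"
            )
    table = m.default_table()
    mode = params.mass_mode
    entries: list[TheoreticalEntry] = []

    pcp_mass: dict[tuple[str, int, int], float] = {}
    for s in subs:
        for frag in enumerate_pcp(s, params.enumeration):
            seq = s.fragment(frag.i, frag.j)
            deltas = {
                p - frag.i + 1: d
                for p, d in (s.label_offsets or {}).items()
                if frag.i <= p <= frag.j
            }
            mr = m.peptide_mass(seq, table, deltas or None, mode)
            pcp_mass[(s.id, frag.i, frag.j)] = mr
            entries.append(
                TheoreticalEntry(
                    "PCP", s.id, None, frag.i, frag.j, None, None, seq, mr,
                    {z: m.mz_value(mr, z, table) for z in params.charges}, None,
                )
            )

    for idx, cls in enumerate_psp(subs if len(subs) > 1 else subs[0], params.enumeration, cross_only):
        mr = m.splice_mass(
            pcp_mass[(idx.substrate_first.id, idx.first.i, idx.first.j)],
            pcp_mass[(idx.substrate_second.id, idx.second.i, idx.second.j)],
            table,
        )
        entries.append(
            TheoreticalEntry(
                "PSP",
                idx.substrate_first.id,
                idx.substrate_second.id,
                idx.first.i, idx.first.j, idx.second.i, idx.second.j,
                sequence_of(idx), mr,
                {z: m.mz_value(mr, z, table) for z in params.charges},
                cls,
            )
        )

    clusters = _cluster_entries(entries, params)
    return TheoreticalDatabase(entries, clusters, params, tuple(s.id for s in subs))


def _cluster_entries(entries: list[TheoreticalEntry], params: DbParams) -> list[MzCluster]:
    pool = [
        (ei, z, e.mz[z])
        for ei, e in enumerate(entries)
        if e.kind == "PSP" or params.include_pcp_in_clusters
        for z in sorted(e.mz)
    ]
    values = [p[2] for p in pool]
    clusters = []
    for cid, group in enumerate(cluster_mz(values, params.cluster_width)):
        clusters.append(
            MzCluster(
                cid,
                [(pool[g][0], pool[g][1]) for g in group],
                [pool[g][2] for g in group],
            )
        )
    return clusters


def db_stats(db: TheoreticalDatabase) -> dict:
    """Per-class entry counts plus the number of m/z clusters."""
    by_class = {c: 0 for c in PspClass}
    for e in db.psp_entries:
        by_class[e.psp_class] += 1
    return {
        "n_pcp": len(db.pcp_entries),
        "n_cis_normal": by_class[PspClass.CIS_NORMAL],
        "n_cis_reverse": by_class[PspClass.CIS_REVERSE],
        "n_trans": by_class[PspClass.TRANS],
        "n_psp": len(db.psp_entries),
        "n_clusters": len(db.clusters),
    }


def to_frame(db: TheoreticalDatabase) -> pd.DataFrame:
    """Flat TSV-ready dump: one row per (entry, charge)."""
    cluster_of: dict[tuple[int, int], MzCluster] = {}
    for c in db.clusters:
        for member in c.members:
            cluster_of[member] = c
    rows = []
    for ei, e in enumerate(db.entries):
        for z in sorted(e.mz):
            c = cluster_of.get((ei, z))
            rows.append(
                {
                    "sequence": e.sequence,
                    "substrate_first": e.substrate_first,
                    "substrate_second": e.substrate_second or "",
                    "i": e.i, "j": e.j,
                    "k": "" if e.k is None else e.k,
                    "n": "" if e.n is None else e.n,
                    "kind": e.kind,
                    "psp_class": str(e.psp_class) if e.psp_class else "",
                    "mr": round(e.mr, 6),
                    "z": z,
                    "mz": round(e.mz[z], 6),
                    "cluster_id": "" if c is None else c.cluster_id,
                    "cluster_mz": "" if c is None else round(c.representative, 6),
                }
            )
    return pd.DataFrame(rows)


def write_tsv(db: TheoreticalDatabase, path: str | Path) -> None:
    to_frame(db).to_csv(path, sep="\t", index=False)


def read_clusters_tsv(path: str | Path) -> pd.DataFrame:
    """Cluster representatives from a database TSV dump (for matching)."""
    df = pd.read_csv(path, sep="\t")
    df = df[df["cluster_id"].notna() & (df["cluster_id"].astype(str) != "")]
    df["cluster_id"] = df["cluster_id"].astype(int)
    return (
        df.groupby("cluster_id", as_index=False)
        .agg(cluster_mz=("cluster_mz", "first"), n_members=("mz", "size"),
             charge=("z", lambda s: int(s.mode().min())))
    )


def export_fasta(
    db: TheoreticalDatabase,
    path: str | Path,
    dedupe_sequences: bool = False,
    include_pcp: bool = True,
) -> int:
    """Write the database as a searchable FASTA; returns the record count.

    Headers encode ``substrate|i-j[/k-n]|kind-or-class|Mr``.  With
    ``dedupe_sequences`` identical sequences collapse into one record whose
    header lists every index provenance, separated by ``;``.
    """
    entries = [e for e in db.entries if include_pcp or e.kind == "PSP"]

    def tag(e: TheoreticalEntry) -> str:
        what = str(e.psp_class) if e.kind == "PSP" else "PCP"
        sub = e.substrate_first if e.substrate_second in (None, e.substrate_first) else (
            f"{e.substrate_first}+{e.substrate_second}"
        )
        return f"{sub}|{e.index_label}|{what}"

    lines: list[str] = []
    count = 0
    if dedupe_sequences:
        merged: dict[str, list[TheoreticalEntry]] = {}
        for e in entries:
            merged.setdefault(e.sequence, []).append(e)
        for seq, group in merged.items():
            header = ";".join(tag(e) for e in group) + f"|Mr={group[0].mr:.4f}"
            lines += [f">{header}", seq]
            count += 1
    else:
        for e in entries:
            lines += [f">{tag(e)}|Mr={e.mr:.4f}", e.sequence]
            count += 1
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return count


def product_counts_of(db: TheoreticalDatabase) -> ProductCounts:
    s = db_stats(db)
    return ProductCounts(
        n_pcp=s["n_pcp"],
        n_cis_normal=s["n_cis_normal"],
        n_cis_reverse=s["n_cis_reverse"],
        n_trans=s["n_trans"],
        n_all_pairs=s["n_pcp"] ** 2 if len(db.substrate_ids) == 1 else -1,
    )


def verify_counts(db: TheoreticalDatabase) -> bool:
    """Single-substrate consistency check against the closed-form counts."""
    if len(db.substrate_ids) != 1:
        raise ValueError("closed-form counts apply to single-substrate databases")
    stats = db_stats(db)
    L = max(e.j for e in db.pcp_entries)
    expected = count_products(L, db.params.enumeration.l_ext)
    return (
        stats["n_pcp"] == expected.n_pcp
        and stats["n_cis_normal"] == expected.n_cis_normal
        and stats["n_cis_reverse"] == expected.n_cis_reverse
        and stats["n_trans"] == expected.n_trans
    )
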