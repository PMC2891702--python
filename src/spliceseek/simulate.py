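"""Reproducible synthetic digestion time-courses with known ground truth.

Planted products follow first-order appearance kinetics, optionally with a
decay term modelling re-degradation of released products:

    I(t) = A * (1 - exp(-k_in * t))                       (saturating)
    I(t) = A * (exp(-k_out * t) - exp(-k_in * t))         (rise-then-fall)

Contaminants are constant-intensity species already present at t = 0.
Decoy peaks are placed at random m/z values kept clear of every
theoretical cluster window so they can never be matched; a flag lifts
that restriction for stress testing.  All randomness derives from a
single seed, so identical configurations produce identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import masses as m
from .database import DbParams, TheoreticalDatabase, build_database
from .enumeration import Substrate
from .io import PEAK_COLUMNS, write_peaklist_csv

# Kyte-Doolittle hydropathy, used only to assign plausible, reproducible RTs.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_TIME_GRID = (0.0, 20.0, 60.0, 180.0, 360.0, 720.0, 1440.0)  # minutes


@dataclass(frozen=True)
class PlantedProduct:
    """One product to plant: a database entry index plus kinetics."""

    entry_index: int
    charge: int = 1
    amplitude: float = 5e6
    k_in: float = 5e-3        # 1/min
    k_out: float | None = None

    def intensity(self, t: float) -> float:
        if self.k_out is None:
            return self.amplitude * (1 - math.exp(-self.k_in * t))
        return self.amplitude * (math.exp(-self.k_out * t) - math.exp(-self.k_in * t))


@dataclass(frozen=True)
class Contaminant:
    mz: float
    intensity: float
    rt_min: float


@dataclass
class SimulationConfig:
    substrates: Sequence[Substrate]
    planted: Sequence[PlantedProduct] = ()
    contaminants: Sequence[Contaminant] = ()
    n_decoys: int = 0
    noise_level: float = 0.0            # relative log-normal jitter on intensities
    decoys_avoid_clusters: bool = True
    time_grid: Sequence[float] = DEFAULT_TIME_GRID
    rt_jitter: float = 0.0              # minutes, sd of RT scatter across times
    seed: int = 0
    db_params: DbParams = field(default_factory=DbParams)

    def __post_init__(self) -> None:
        if not self.time_grid:
            raise ValueError("time grid must be non-empty")
        grid = sorted(self.time_grid)
        if grid[0] != 0:
            raise ValueError("time grid must start at 0")


def retention_time(sequence: str, rng: np.random.Generator | None = None, jitter: float = 0.0) -> float:
    """Hydropathy-proportional RT in minutes (arbitrary but reproducible)."""
    kd = sum(_KD[a] for a in sequence) / len(sequence)
    rt = 25.0 + 4.0 * kd + 0.35 * len(sequence)
    if rng is not None and jitter > 0:
        rt += rng.normal(0, jitter)
    return max(rt, 1.0)


@dataclass
class TruthManifest:
    """Ground truth for every planted product, consistent with the files."""

    frame: pd.DataFrame      # one row per planted product
    cluster_of: dict[int, int]   # planted entry index -> cluster id

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def simulate_digest(
    config: SimulationConfig,
    database: TheoreticalDatabase | None = None,
) -> tuple[dict[float, pd.DataFrame], TruthManifest]:
    """Emit per-digestion-time peak lists plus the ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    db = database or build_database(list(config.substrates), config.db_params)
    grid = sorted(set(float(t) for t in config.time_grid))

    cluster_of_member = {
        member: c.cluster_id for c in db.clusters for member in c.members
    }
    cluster_rep = {c.cluster_id: c.representative for c in db.clusters}

    truth_rows = []
    cluster_of: dict[int, int] = {}
    signal_rows: dict[float, list[tuple[float, float, float]]] = {t: [] for t in grid}

    for p in config.planted:
        e = db.entries[p.entry_index]
        if p.charge not in e.mz:
            raise ValueError(f"charge {p.charge} not in database charge set")
        mz = e.mz[p.charge]
        cid = cluster_of_member.get((p.entry_index, p.charge))
        rt = retention_time(e.sequence, rng, config.rt_jitter)
        samples = []
        for t in grid:
            inten = p.intensity(t)
            if config.noise_level > 0 and inten > 0:
                inten *= float(np.exp(rng.normal(0, config.noise_level)))
            samples.append((t, inten))
            if inten > 0:
                signal_rows[t].append((mz, rt, inten))
        if cid is not None:
            cluster_of[p.entry_index] = cid
        truth_rows.append(
            {
                "entry_index": p.entry_index,
                "substrate_first": e.substrate_first,
                "substrate_second": e.substrate_second or "",
                "indices": e.index_label,
                "kind": e.kind,
                "psp_class": str(e.psp_class) if e.psp_class else "",
                "sequence": e.sequence,
                "mr": e.mr,
                "charge": p.charge,
                "mz": mz,
                "cluster_id": -1 if cid is None else cid,
                "cluster_mz": float("nan") if cid is None else cluster_rep[cid],
                "rt_min": rt,
                "t_max": max(samples, key=lambda s: s[1])[0],
                "kinetics": ";".join(f"{t:g}:{v:.2f}" for t, v in samples),
            }
        )

    for c in config.contaminants:
        for t in grid:
            signal_rows[t].append((c.mz, c.rt_min, c.intensity))

    if config.n_decoys:
        forbidden = sorted(cluster_rep.values())
        margin = config.db_params.cluster_width + 0.6  # tolerance + safety
        decoy_mz = []
        while len(decoy_mz) < config.n_decoys:
            cand = float(rng.uniform(250.0, 2000.0))
            if config.decoys_avoid_clusters and forbidden:
                ix = np.searchsorted(forbidden, cand)
                near = [
                    forbidden[q] for q in (ix - 1, ix) if 0 <= q < len(forbidden)
                ]
                if any(abs(cand - f) < margin for f in near):
                    continue
            decoy_mz.append(cand)
        for dmz in decoy_mz:
            rt = float(rng.uniform(5.0, 60.0))
            t_hit = float(rng.choice([t for t in grid if t > 0]))
            signal_rows[t_hit].append((dmz, rt, float(rng.uniform(1e4, 5e5))))

    peaklists = {}
    for t in grid:
        rows = sorted(signal_rows[t])
        peaklists[t] = pd.DataFrame(
            [(mz, rt, inten, t) for mz, rt, inten in rows], columns=PEAK_COLUMNS
        )
    manifest = TruthManifest(pd.DataFrame(truth_rows), cluster_of)
    return peaklists, manifest


def write_simulation(
    peaklists: dict[float, pd.DataFrame],
    manifest: TruthManifest,
    outdir: str | Path,
) -> list[Path]:
    """Write one CSV per digestion time plus the manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in sorted(peaklists):
        p = outdir / f"peaks_t{t:07.1f}min.csv"
        write_peaklist_csv(peaklists[t], p)
        written.append(p)
    manifest.to_tsv(outdir / "manifest.tsv")
    written.append(outdir / "manifest.tsv")
    return written


def end_to_end_fixture(
    substrate: Substrate,
    n_planted: int,
    n_decoys: int,
    seed: int,
    db_params: DbParams | None = None,
) -> tuple[SimulationConfig, TheoreticalDatabase, dict[float, pd.DataFrame], TruthManifest]:
    """A ready-to-screen fixture with saturating-kinetics plants.

    Planted entries are drawn (reproducibly) from the splice products of
    the substrate; amplitudes sit well above noise and below the t = 0
    ceiling, so the screening stages must recover exactly the planted
    clusters.
    """
    db_params = db_params or DbParams()
    db = build_database(substrate, db_params)
    psp_indices = [ei for ei, e in enumerate(db.entries) if e.kind == "PSP"]
    if n_planted > len(psp_indices):
        raise ValueError("more plants requested than splice products available")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(psp_indices, size=n_planted, replace=False).tolist())
    planted = [
        PlantedProduct(ei, charge=1, amplitude=float(rng.uniform(2e6, 8e6)), k_in=4e-3)
        for ei in chosen
    ]
    config = SimulationConfig(
        substrates=[substrate],
        planted=planted,
        n_decoys=n_decoys,
        seed=seed,
        db_params=db_params,
    )
    peaklists, manifest = simulate_digest(config, db)
    return config, db, peaklists, manifest
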