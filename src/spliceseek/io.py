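"""Readers and writers for substrates, peak lists and enumeration dumps.

Peak lists are centroided MS1 observations with four columns:
``mz``, ``rt_min``, ``intensity``, ``digestion_time`` (minutes).  The CSV
dialect is the native one; a minimal MGF dialect (one pseudo-spectrum per
(digestion time, retention time) scan) is supported for interchange.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enumeration import Substrate

PEAK_COLUMNS = ["mz", "rt_min", "intensity", "digestion_time"]


def concat_peaklists(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate observation tables, tolerating empty ones (e.g. t = 0)."""
    nonempty = [f[PEAK_COLUMNS] for f in frames if len(f)]
    if not nonempty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    return pd.concat(nonempty, ignore_index=True)


def read_substrates(path: str | Path) -> list[Substrate]:
    """Read substrates from FASTA (``>`` header) or plain text.

    Plain text: one substrate per line, either ``id<TAB or space>sequence``
    or a bare sequence (auto-named ``substrate_1``, ``substrate_2``...).
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [
            Substrate(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    subs = []
    for idx, line in enumerate((ln.strip() for ln in text.splitlines()), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) >= 2:
            subs.append(Substrate(parts[0], parts[1].upper()))
        else:
            subs.append(Substrate(f"substrate_{idx}", parts[0].upper()))
    if not subs:
        raise ValueError(f"no substrates found in {path}")
    return subs


def write_substrates_fasta(substrates: Iterable[Substrate], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in substrates]
    SeqIO.write(records, str(path), "fasta")


def read_peaklist_csv(paths: str | Path | Sequence[str | Path]) -> pd.DataFrame:
    """Load one or more peak-list CSVs into a single observation table."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no peak lists given")
    frames = []
    for p in paths:
        df = pd.read_csv(p)
        missing = set(PEAK_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{p}: peak list missing columns {sorted(missing)}")
        frames.append(df[PEAK_COLUMNS])
    out = concat_peaklists(frames)
    if (out["intensity"] < 0).any() or (out["rt_min"] < 0).any():
        raise ValueError("peak list contains negative intensity or retention time")
    return out


def write_peaklist_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[PEAK_COLUMNS].to_csv(path, index=False)


def write_peaklist_mgf(df: pd.DataFrame, path: str | Path) -> None:
    """MS1 observations as MGF pseudo-spectra, one per (time, RT) scan."""
    lines: list[str] = []
    for (t, rt), grp in df.groupby(["digestion_time", "rt_min"], sort=True):
        lines.append("BEGIN IONS")
        lines.append(f"TITLE=digestion_time={t:g};rt_min={rt:g}")
        lines.append(f"RTINSECONDS={rt * 60:.4f}")
        for _, row in grp.sort_values("mz").iterrows():
            lines.append(f"{row['mz']:.5f} {row['intensity']:.4f}")
        lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")


_TITLE_RE = re.compile(r"digestion_time=([^;]+);rt_min=(.+)")


def read_peaklist_mgf(path: str | Path) -> pd.DataFrame:
    rows = []
    t = rt = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line == "BEGIN IONS":
            continue
        if line == "END IONS":
            t = rt = None
            continue
        if line.startswith("TITLE="):
            m = _TITLE_RE.search(line)
            if not m:
                raise ValueError(f"unparseable MGF title: {line}")
            t, rt = float(m.group(1)), float(m.group(2))
            continue
        if "=" in line:
            continue
        if t is None:
            raise ValueError("MGF peak line outside of an ion block")
        mz, intensity = line.split()[:2]
        rows.append((float(mz), rt, float(intensity), t))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def load_peaklists(paths: Sequence[str | Path]) -> pd.DataFrame:
    """Dispatch on extension (.csv or .mgf) and concatenate."""
    frames = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".mgf":
            frames.append(read_peaklist_mgf(p))
        else:
            frames.append(read_peaklist_csv(p))
    if not frames:
        raise ValueError("no peak lists given")
    return concat_peaklists(frames)
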