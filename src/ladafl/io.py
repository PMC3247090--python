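"""Marker-table readers, segment writers and run configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .inference import DetectionConfig, Segment, SegmentTest
from .profile import CGHProfile


class MarkerTableError(ValueError):
    pass


def read_marker_table(path) -> pd.DataFrame:
    """Read a marker table as TSV.

    Accepts either a headered table with a ``log2ratio`` column (and
    optional ``chrom`` / ``pos`` columns) or a bare single column of
    ratios, in which case positions 1..n are assigned.  The table must
    contain a single chromosome, sorted by position.
    """
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise MarkerTableError(f"{path}: empty file") from None
    if "log2ratio" not in table.columns:
        # single column, no header: re-read as bare values
        table = pd.read_csv(path, sep="\t", header=None)
        if table.shape[1] != 1:
            raise MarkerTableError(
                f"{path}: expected a 'log2ratio' column or a single bare column"
            )
        table.columns = ["log2ratio"]
    ratios = pd.to_numeric(table["log2ratio"], errors="coerce")
    if ratios.isna().any():
        row = int(ratios.index[ratios.isna()][0]) + 2  # 1-based + header
        raise MarkerTableError(f"{path}: non-numeric log2 ratio at line {row}")
    table["log2ratio"] = ratios.astype(float)
    if "chrom" in table.columns:
        chroms = table["chrom"].unique()
        if len(chroms) > 1:
            row = int(np.flatnonzero(table["chrom"] != chroms[0])[0]) + 2
            raise MarkerTableError(
                f"{path}: multiple chromosomes (line {row} has {table['chrom'].iloc[row-2]!r});"
                " analyze one chromosome per run"
            )
    if "pos" in table.columns:
        pos = pd.to_numeric(table["pos"], errors="coerce")
        if pos.isna().any() or (pos.diff().dropna() <= 0).any():
            raise MarkerTableError(f"{path}: positions must be numeric and increasing")
        table["pos"] = pos.astype(np.int64)
    else:
        table["pos"] = np.arange(1, len(table) + 1)
    return table


def table_to_profile(table: pd.DataFrame) -> CGHProfile:
    chrom = str(table["chrom"].iloc[0]) if "chrom" in table.columns else None
    return CGHProfile(
        values=table["log2ratio"].to_numpy(),
        positions=table["pos"].to_numpy(),
        chrom=chrom,
    )


def write_segments(
    segments: list[Segment],
    tests: list[SegmentTest],
    path,
    fmt: str = "tsv",
    p_cutoff: float = 0.002,
    chrom: str = "chr?",
) -> None:
    """Write per-segment results as TSV (1-based inclusive) or BED.

    BED lines use 0-based half-open coordinates; the name field carries
    the fitted segment level so the conversion round-trips exactly.
    """
    by_index = {t.index: t for t in tests}
    rows = [
        {
            "start": s.start,
            "end": s.end,
            "n_k": s.n_k,
            "beta_median": s.beta_median,
            "z": by_index[s.index].z,
            "p": by_index[s.index].p,
            "significant": int(by_index[s.index].p <= p_cutoff),
        }
        for s in segments
    ]
    frame = pd.DataFrame(
        rows, columns=["start", "end", "n_k", "beta_median", "z", "p", "significant"]
    )
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif fmt == "bed":
        bed = pd.DataFrame(
            {
                "chrom": chrom,
                "start": frame["start"] - 1,
                "end": frame["end"],
                "name": frame["beta_median"].map("level={:.12g}".format),
                "score": frame["significant"] * 1000,
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


@dataclass
class RunConfig:
    """Resolved settings of one analysis run, serialized for provenance."""

    method: str = "lad-afl"
    lambda1: float | None = None
    lambda2: float | None = None
    auto_tune: bool = True
    q1: float = 3.0
    q2: float = 2.0
    b0: float = 0.1
    p_cutoff: float = 0.002
    seed: int = 0
    chunk_size: int | None = None

    def detection(self) -> DetectionConfig:
        return DetectionConfig(b0=self.b0, p_cutoff=self.p_cutoff)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
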