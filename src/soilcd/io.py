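"""Shared data model and file readers/writers.

Tabular interchange formats are deliberately plain text:

* count table — TSV, ``taxon_id<TAB>lineage<TAB><sample ids...>``, integer cells
* sample metadata — CSV with one row per sample
* thermogram — CSV with a ``#``-comment header block declaring
  ``sample_id``, ``treatment`` and ``time_unit`` (h or s), then
  ``time,heat_flow_mW`` columns

All writers prepend a provenance comment (config hash + seed) and all
readers skip ``#`` lines, so outputs of one stage are inputs of the next.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "Thermogram",
    "CountTableError",
    "ThermogramError",
    "MetadataError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_thermogram",
    "write_thermogram",
    "REQUIRED_METADATA_COLUMNS",
]


class CountTableError(ValueError):
    """Malformed or invalid ASV count table."""


class ThermogramError(ValueError):
    """Malformed or invalid thermogram file."""


class MetadataError(ValueError):
    """Malformed or incomplete sample metadata."""


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------

RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class CountTable:
    """Integer ASV-by-sample abundance matrix with per-taxon lineage.

    Parameters
    ----------
    taxon_ids : sequence of str
        Unique opaque ASV identifiers (row labels).
    lineage : sequence of str
        Rank-labelled taxonomic path per taxon, e.g.
        ``d__Bacteria;p__Pseudomonadota;...;g__Cupriavidus``.
    samples : sequence of str
        Unique sample identifiers (column labels).
    counts : ndarray
        Non-negative integer matrix of shape ``(n_taxa, n_samples)``.
    """

    taxon_ids: list[str]
    lineage: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.lineage = [str(x) for x in self.lineage]
        self.samples = [str(s) for s in self.samples]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountTableError("counts must be a 2-D matrix (taxa x samples)")
        if self.counts.shape != (len(self.taxon_ids), len(self.samples)):
            raise CountTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.samples)} samples"
            )
        if len(self.lineage) != len(self.taxon_ids):
            raise CountTableError("lineage length does not match taxon count")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.round(self.counts)
            if not np.allclose(self.counts, rounded, atol=0, rtol=0):
                bad = np.argwhere(self.counts != rounded)[0]
                raise CountTableError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.samples[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise CountTableError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dupes = {t for t in self.taxon_ids if self.taxon_ids.count(t) > 1}
            raise CountTableError(f"duplicate taxon ids: {sorted(dupes)[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise CountTableError("duplicate sample ids")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def check_no_empty_samples(self) -> None:
        """Raise if any sample column is all-zero (undefined composition)."""
        col = self.counts.sum(axis=0)
        if (col == 0).any():
            empty = [s for s, c in zip(self.samples, col) if c == 0]
            raise CountTableError(f"all-zero sample column(s): {empty}")

    def relative_abundance(self) -> np.ndarray:
        """Per-sample proportions; requires no all-zero sample."""
        self.check_no_empty_samples()
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def select_samples(self, keep: Sequence[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in keep]
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx].copy(),
        )

    def aggregate_rank(self, rank: str) -> "CountTable":
        """Sum counts within each lineage truncated at *rank*.

        ``rank`` is one of domain/phylum/class/order/family/genus. The
        aggregated table uses the truncated lineage string as both taxon id
        and lineage; taxa whose lineage lacks the rank are pooled under
        ``unclassified``.
        """
        if rank not in RANK_NAMES:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANK_NAMES}")
        depth = RANK_NAMES.index(rank) + 1
        keys: list[str] = []
        for lin in self.lineage:
            parts = [p.strip() for p in lin.split(";")]
            key = ";".join(parts[:depth]) if len(parts) >= depth else "unclassified"
            keys.append(key)
        order = list(dict.fromkeys(keys))
        mat = np.zeros((len(order), self.n_samples), dtype=np.int64)
        pos = {k: i for i, k in enumerate(order)}
        for row, key in enumerate(keys):
            mat[pos[key]] += self.counts[row]
        return CountTable(order, order, list(self.samples), mat)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.samples)
        df.insert(0, "lineage", self.lineage)
        df.index.name = "taxon_id"
        return df


def write_count_table(
    table: CountTable, path: str | Path, provenance: str | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("taxon_id\tlineage\t" + "\t".join(table.samples) + "\n")
        for tid, lin, row in zip(table.taxon_ids, table.lineage, table.counts):
            fh.write(tid + "\t" + lin + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (first column taxon id, optional lineage column).

    The lineage column is recognised by the header name ``lineage``; when
    absent, lineages default to the empty string.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise CountTableError(f"{path}: empty count table")
    header = lines[0].rstrip("\n").split("\t")
    has_lineage = len(header) > 1 and header[1] == "lineage"
    first_data_col = 2 if has_lineage else 1
    samples = header[first_data_col:]
    taxon_ids: list[str] = []
    lineages: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.rstrip("\n").split("\t")
        if len(cells) != len(header):
            raise CountTableError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        taxon_ids.append(cells[0])
        lineages.append(cells[1] if has_lineage else "")
        row = []
        for col, cell in zip(samples, cells[first_data_col:]):
            try:
                val = int(cell)
            except ValueError:
                raise CountTableError(
                    f"{path}:{lineno}: non-integer count {cell!r} in column {col!r}"
                ) from None
            if val < 0:
                raise CountTableError(
                    f"{path}:{lineno}: negative count {val} in column {col!r}"
                )
            row.append(val)
        rows.append(row)
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(samples)), int)
    return CountTable(taxon_ids, lineages, samples, counts)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

REQUIRED_METADATA_COLUMNS = ("sample_id", "farm", "plot", "cd_soil", "treatment")
OPTIONAL_METADATA_COLUMNS = ("timepoint", "depth_target")
VALID_TREATMENTS = ("control", "spiked")
VALID_TIMEPOINTS = ("S", "P", "E")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata frame in place and return it.

    Missing required fields are errors, not defaults; ``timepoint`` may be
    empty (a field sample rather than an assay subsample).
    """
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata missing required column(s): {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample_id rows: {dupes[:5]}")
    cd = pd.to_numeric(meta["cd_soil"], errors="coerce")
    if cd.isna().any() or not np.isfinite(cd).all():
        raise MetadataError("cd_soil must be finite numbers")
    if (cd < 0).any():
        raise MetadataError("cd_soil must be >= 0 (mg kg^-1)")
    meta = meta.copy()
    meta["cd_soil"] = cd.astype(float)
    bad = set(meta["treatment"]) - set(VALID_TREATMENTS)
    if bad:
        raise MetadataError(f"unknown treatment value(s): {sorted(bad)}")
    if "timepoint" in meta.columns:
        tp = meta["timepoint"].fillna("")
        bad_tp = set(tp) - set(VALID_TIMEPOINTS) - {""}
        if bad_tp:
            raise MetadataError(f"unknown timepoint value(s): {sorted(bad_tp)}")
    return meta


def check_metadata_covers(table: CountTable, meta: pd.DataFrame) -> None:
    """Every sample in the count table must have exactly one metadata row."""
    ids = set(meta["sample_id"])
    missing = [s for s in table.samples if s not in ids]
    if missing:
        raise MetadataError(f"samples without metadata: {missing[:5]}")


def write_metadata(
    meta: pd.DataFrame, path: str | Path, provenance: str | None = None
) -> None:
    with Path(path).open("w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        meta.to_csv(fh, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, comment="#", dtype={"sample_id": str, "plot": str})
    return validate_metadata(meta)


# ---------------------------------------------------------------------------
# thermograms
# ---------------------------------------------------------------------------


@dataclass
class Thermogram:
    """Heat-flow-versus-time record of one calorimeter ampoule.

    ``time`` is in hours (strictly increasing), ``heat_flow`` in mW.
    Negative flows are legal: the instrument's blank subtraction can dip
    below baseline and a negative spiked-minus-control delta is meaningful.
    """

    sample_id: str
    treatment: str
    time: np.ndarray
    heat_flow: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.time.shape != self.heat_flow.shape or self.time.ndim != 1:
            raise ThermogramError("time and heat_flow must be 1-D arrays of equal length")
        if not (np.isfinite(self.time).all() and np.isfinite(self.heat_flow).all()):
            raise ThermogramError("non-finite values in thermogram")
        if len(self.time) >= 2 and not (np.diff(self.time) > 0).all():
            raise ThermogramError("time must be strictly increasing")
        if self.treatment not in VALID_TREATMENTS:
            raise ThermogramError(f"treatment must be one of {VALID_TREATMENTS}")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self.time) else 0.0


def write_thermogram(
    tg: Thermogram, path: str | Path, provenance: str | None = None
) -> None:
    with Path(path).open("w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write(f"# sample_id={tg.sample_id}\n")
        fh.write(f"# treatment={tg.treatment}\n")
        fh.write("# time_unit=h\n")
        fh.write("time,heat_flow_mW\n")
        for t, q in zip(tg.time, tg.heat_flow):
            fh.write(f"{t:.9g},{q:.9g}\n")


def read_thermogram(path: str | Path) -> Thermogram:
    """Read a thermogram CSV.

    The comment block must declare ``time_unit`` (h or s); a missing unit is
    an error — the loader never guesses. Seconds are converted to hours.
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    for ln in path.read_text().splitlines():
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
        elif ln.strip():
            data_lines.append(ln)
    if "time_unit" not in header:
        raise ThermogramError(f"{path}: missing '# time_unit=h|s' declaration")
    unit = header["time_unit"]
    if unit not in ("h", "s"):
        raise ThermogramError(f"{path}: unknown time unit {unit!r} (expected h or s)")
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    if "time" not in df.columns or "heat_flow_mW" not in df.columns:
        raise ThermogramError(f"{path}: expected columns time,heat_flow_mW")
    t = df["time"].to_numpy(float)
    if unit == "s":
        t = t / 3600.0
    if len(t) >= 2 and not (np.diff(t) > 0).all():
        raise ThermogramError(f"{path}: time not strictly increasing")
    return Thermogram(
        sample_id=header.get("sample_id", path.stem),
        treatment=header.get("treatment", "control"),
        time=t,
        heat_flow=df["heat_flow_mW"].to_numpy(float),
    )
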