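"""Input/output for the formats the pipeline touches.

External formats are all tab-separated, header-less text following BED
conventions (0-based half-open coordinates):

* contacts — BED-like with >=4 columns, column 4 holding the RNA name; each
  record is the DNA part of one RNA-DNA contact;
* chromosome sizes — two columns, name and length in bp;
* gene annotation — BED6-like, column 4 is the (unique) gene name;
* background track — 4-column bedGraph at a uniform fine resolution;
* peak calls — ENCODE narrowPeak (10 columns).

Intermediates persist in a hierarchical HDF5 container, one group per RNA,
with a schema version string (see :func:`store_dataset`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: schema identifier written to every container; bumped on layout changes
CONTAINER_SCHEMA = "rdpeaks-container-v1"

#: cap for -log10(p) / -log10(q) columns in narrowPeak output, so q = 0
#: never emits infinity
NEGLOG_CAP = 400.0

CONTACT_COLUMNS = ["chrom", "start", "end", "rna_name"]


class FormatError(ValueError):
    """A malformed input file (names the offending line where possible)."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene from the annotation; the RNA source gene for cis binning."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."
    biotype: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.name!r}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class FineTrack:
    """Uniform fine-resolution per-bin values tiling each chromosome.

    ``values[chrom]`` has ``ceil(length / binsize)`` entries; the last bin is
    implicitly truncated at the chromosome end.
    """

    binsize: int
    chromsizes: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, length in self.chromsizes.items():
            n = -(-length // self.binsize)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n)
            elif len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.values[chrom])}"
                )
        for chrom, vals in self.values.items():
            if np.any(vals < 0):
                raise ValueError(f"{chrom}: negative track values")

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def min_nonzero(self) -> float:
        """Smallest positive fine-bin value (used for zero imputation)."""
        nz = [v[v > 0] for v in self.values.values()]
        nz = [v for v in nz if v.size]
        if not nz:
            return 0.0
        return float(min(v.min() for v in nz))

    def scaled(self, c: float) -> "FineTrack":
        return FineTrack(
            self.binsize,
            dict(self.chromsizes),
            {k: v * c for k, v in self.values.items()},
        )


# ---------------------------------------------------------------------------
# readers


def _read_table(path, min_cols: int, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty %s file", path, what)
        return pd.DataFrame()
    if df.shape[1] < min_cols:
        raise FormatError(
            f"{path}: {what} needs >= {min_cols} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    return df


def _to_int(series: pd.Series, path, what: str) -> np.ndarray:
    try:
        return series.astype(np.int64).to_numpy()
    except (ValueError, TypeError):
        bad = series[pd.to_numeric(series, errors="coerce").isna()]
        line = bad.index[0] + 1 if len(bad) else "?"
        raise FormatError(f"{path}: non-integer {what} at line {line}") from None


def read_chromsizes(path) -> dict[str, int]:
    """Read a two-column chromosome-sizes file into ``{name: length}``."""
    df = _read_table(path, 2, "chromsizes")
    if df.empty:
        raise FormatError(f"{path}: empty chromsizes file")
    names = df[0].tolist()
    lengths = _to_int(df[1], path, "length")
    dupes = df[0][df[0].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate chromosomes: {', '.join(dupes)}")
    if np.any(lengths <= 0):
        line = int(np.nonzero(lengths <= 0)[0][0]) + 1
        raise FormatError(f"{path}: non-positive length at line {line}")
    return dict(zip(names, (int(x) for x in lengths)))


def read_contacts(path, chromsizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Read DNA parts of contacts (BED-like, column 4 = RNA name).

    Extra columns (score, strand, ...) are accepted and ignored. Returns a
    DataFrame with columns chrom/start/end/rna_name, input order preserved
    within each RNA.
    """
    df = _read_table(path, 4, "contacts")
    if df.empty:
        return pd.DataFrame(columns=CONTACT_COLUMNS)
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": _to_int(df[1], path, "start"),
            "end": _to_int(df[2], path, "end"),
            "rna_name": df[3].astype(str),
        }
    )
    validate_contacts(out, chromsizes, origin=str(path))
    return out


def validate_contacts(
    contacts: pd.DataFrame, chromsizes: dict[str, int] | None = None, origin="contacts"
) -> None:
    """Enforce contact invariants: 0 <= start < end (<= chrom length)."""
    bad = (contacts["start"] < 0) | (contacts["start"] >= contacts["end"])
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise FormatError(f"{origin}: start >= end (or negative) at line {line}")
    if (contacts["rna_name"].astype(str).str.len() == 0).any():
        raise FormatError(f"{origin}: empty RNA name")
    if chromsizes is not None:
        unknown = set(contacts["chrom"]) - set(chromsizes)
        if unknown:
            raise FormatError(
                f"{origin}: chromosomes absent from chromsizes: {sorted(unknown)}"
            )
        lengths = contacts["chrom"].map(chromsizes)
        over = contacts["end"] > lengths
        if over.any():
            line = int(np.nonzero(over.to_numpy())[0][0]) + 1
            raise FormatError(f"{origin}: interval beyond chromosome end at line {line}")


def read_annotation(path) -> dict[str, GeneRecord]:
    """Read a BED6-like gene annotation keyed by unique gene name.

    An optional 7th column is taken as the gene biotype (used to pick
    protein-coding genes for the mRNA background).
    """
    df = _read_table(path, 4, "annotation")
    if df.empty:
        return {}
    names = df[3].astype(str)
    dupes = names[names.duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene names: {', '.join(dupes[:10])}")
    starts = _to_int(df[1], path, "start")
    ends = _to_int(df[2], path, "end")
    strands = df[5].astype(str) if df.shape[1] > 5 else ["."] * len(df)
    biotypes = df[6].astype(str) if df.shape[1] > 6 else [None] * len(df)
    genes = {}
    for chrom, s, e, name, strand, bio in zip(
        df[0].astype(str), starts, ends, names, strands, biotypes
    ):
        genes[name] = GeneRecord(chrom, int(s), int(e), name, strand, bio)
    return genes


def read_bedgraph(path, chromsizes: dict[str, int], binsize: int | None = None) -> FineTrack:
    """Read a 4-column bedGraph of uniform bins into a :class:`FineTrack`.

    Gaps are zero-filled; overlapping records are an error. ``binsize`` is
    inferred from the most common record width when not given.
    """
    df = _read_table(path, 4, "bedGraph")
    if df.empty:
        raise FormatError(f"{path}: empty bedGraph")
    chrom = df[0].astype(str).to_numpy()
    start = _to_int(df[1], path, "start")
    end = _to_int(df[2], path, "end")
    value = pd.to_numeric(df[3], errors="coerce").to_numpy(float)
    if np.isnan(value).any():
        line = int(np.nonzero(np.isnan(value))[0][0]) + 1
        raise FormatError(f"{path}: non-numeric value at line {line}")
    if binsize is None:
        widths = end - start
        binsize = int(pd.Series(widths).mode().iloc[0])
    track = FineTrack(binsize, dict(chromsizes))
    order = np.lexsort((start, chrom))
    for c in np.unique(chrom):
        if c not in chromsizes:
            raise FormatError(f"{path}: unknown chromosome {c!r}")
    prev_chrom, prev_end = None, 0
    for i in order:
        c, s, e, v = chrom[i], int(start[i]), int(end[i]), value[i]
        if c == prev_chrom and s < prev_end:
            raise FormatError(f"{path}: overlapping bedGraph records on {c} at {s}")
        prev_chrom, prev_end = c, e
        if s % binsize or (e - s) > binsize:
            # tolerate truncated last bin; anything else breaks the fine grid
            if e != chromsizes[c]:
                raise FormatError(
                    f"{path}: record [{s},{e}) on {c} does not align to "
                    f"{binsize} bp bins"
                )
        track.values[c][s // binsize] = v
    return track


# ---------------------------------------------------------------------------
# narrowPeak

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def neglog10(x: np.ndarray, cap: float = NEGLOG_CAP) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.minimum(-np.log10(np.asarray(x, float)), cap)


def write_narrowpeak(peaks: pd.DataFrame, path, q_threshold: float = 0.05) -> pd.DataFrame:
    """Write bins passing the global q-value threshold as narrowPeak.

    ``peaks`` needs columns chrom/start/end/rna_name/pvalue/qvalue_global and
    ``fold`` (observed over expected count). Returns the formatted frame that
    was written.
    """
    sub = peaks[peaks["qvalue_global"] < q_threshold] if len(peaks) else peaks
    q = neglog10(sub["qvalue_global"].to_numpy()) if len(sub) else np.array([])
    out = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy() if len(sub) else [],
            "start": sub["start"].to_numpy() if len(sub) else [],
            "end": sub["end"].to_numpy() if len(sub) else [],
            "name": sub["rna_name"].to_numpy() if len(sub) else [],
            "score": np.minimum(1000, np.round(10 * q)).astype(int) if len(sub) else [],
            "strand": ".",
            "signalValue": sub["fold"].round(6).to_numpy() if len(sub) else [],
            "pValue": np.round(neglog10(sub["pvalue"].to_numpy()), 6) if len(sub) else [],
            "qValue": np.round(q, 6) if len(sub) else [],
            "peak": -1,
        },
        columns=NARROWPEAK_COLUMNS,
    )
    out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    out.to_csv(path, sep="\t", header=False, index=False)
    return out


def read_narrowpeak(path) -> pd.DataFrame:
    """Strictly parse a narrowPeak file (10 columns, valid types/ranges)."""
    df = _read_table(path, 10, "narrowPeak")
    if df.empty:
        return pd.DataFrame(columns=NARROWPEAK_COLUMNS)
    if df.shape[1] != 10:
        raise FormatError(f"{path}: narrowPeak must have exactly 10 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": _to_int(df[1], path, "start"),
            "end": _to_int(df[2], path, "end"),
            "name": df[3].astype(str),
            "score": _to_int(df[4], path, "score"),
            "strand": df[5].astype(str),
            "signalValue": df[6].astype(float),
            "pValue": df[7].astype(float),
            "qValue": df[8].astype(float),
            "peak": _to_int(df[9], path, "peak"),
        }
    )
    if ((out["start"] < 0) | (out["start"] >= out["end"])).any():
        raise FormatError(f"{path}: invalid narrowPeak interval")
    if ((out["score"] < 0) | (out["score"] > 1000)).any():
        raise FormatError(f"{path}: narrowPeak score outside [0, 1000]")
    if not out["strand"].isin([".", "+", "-"]).all():
        raise FormatError(f"{path}: invalid strand")
    return out


# ---------------------------------------------------------------------------
# HDF5 container
#
# Layout:
#   /                     attrs: schema, package_version, stages (list)
#   /chroms/name, length
#   /rnas/<rna>           attrs: scalar metadata (N_i, trans_binsize, ...)
#   /rnas/<rna>/<array>   per-bin arrays: chrom_idx, bin_start, bin_end,
#                         is_cis, is_gene_body, distance, count, bg_prob,
#                         scaling, prob, pvalue, qvalue_global, qvalue_rna

_STR = h5py.string_dtype(encoding="utf-8")


def store_dataset(state: dict, path) -> None:
    """Persist pipeline state {meta, chromsizes, rnas: {name: {attrs, arrays}}}."""
    from . import __version__

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = CONTAINER_SCHEMA
        f.attrs["package_version"] = __version__
        for key, val in state.get("meta", {}).items():
            f.attrs[key] = val
        chroms = f.create_group("chroms")
        names = list(state["chromsizes"])
        chroms.create_dataset("name", data=np.array(names, dtype=_STR))
        chroms.create_dataset(
            "length", data=np.array([state["chromsizes"][n] for n in names], np.int64)
        )
        rnas = f.create_group("rnas")
        for rna, payload in state.get("rnas", {}).items():
            g = rnas.create_group(rna)
            for key, val in payload.get("attrs", {}).items():
                g.attrs[key] = val
            for key, arr in payload.get("arrays", {}).items():
                arr = np.asarray(arr)
                if arr.dtype.kind in "OU":
                    arr = arr.astype(_STR)
                g.create_dataset(key, data=arr)


def load_dataset(path) -> dict:
    """Load a container written by :func:`store_dataset` (schema-checked)."""
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema")
        if schema != CONTAINER_SCHEMA:
            raise FormatError(
                f"{path}: container schema {schema!r} does not match "
                f"{CONTAINER_SCHEMA!r}"
            )
        meta = {
            k: v for k, v in f.attrs.items() if k not in ("schema", "package_version")
        }
        names = [x.decode() if isinstance(x, bytes) else str(x) for x in f["chroms/name"][:]]
        lengths = f["chroms/length"][:]
        chromsizes = {n: int(l) for n, l in zip(names, lengths)}
        rnas = {}
        for rna, g in f["rnas"].items():
            arrays = {}
            for key, ds in g.items():
                arr = ds[:]
                if arr.dtype.kind in "OS":
                    arr = np.array([x.decode() if isinstance(x, bytes) else x for x in arr])
                arrays[key] = arr
            rnas[rna] = {"attrs": dict(g.attrs), "arrays": arrays}
    return {"meta": meta, "chromsizes": chromsizes, "rnas": rnas}


def write_bedgraph(track: FineTrack, path) -> None:
    """Write a FineTrack as bedGraph (all bins, including zeros)."""
    rows = []
    for chrom, length in track.chromsizes.items():
        vals = track.values[chrom]
        starts = np.arange(len(vals)) * track.binsize
        ends = np.minimum(starts + track.binsize, length)
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": vals})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", header=False, index=False)


def write_bed(df: pd.DataFrame, path, columns: Iterable[str]) -> None:
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)
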