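"""Reading, validation and writing of nCounter-style count data.

The pipeline's in-memory model mirrors how an nCounter CodeSet is organised:
a probe panel (endogenous, positive spike-in, negative, housekeeping probes),
a probes x lanes count matrix, and per-lane sample metadata assigning each
lane to a biological group (cHCL, vHCL, nMNC, nB).

Counts move through three states -- ``raw`` -> ``background_corrected`` ->
``normalized`` -- and every transforming operation appends a line to the
matrix's audit log so the provenance of a table is always reconstructable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hclsig")

PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")
GROUPS = ("cHCL", "vHCL", "nMNC", "nB", "other")
STATES = ("raw", "positive_scaled", "background_corrected", "normalized")

#: RCC CodeClass labels mapped onto the pipeline's probe classes.
_RCC_CLASS_MAP = {
    "endogenous": "endogenous",
    "positive": "positive",
    "negative": "negative",
    "housekeeping": "housekeeping",
}


class PanelIOError(ValueError):
    """Raised for malformed count tables, panels or metadata."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbePanel:
    """Probe annotation for one CodeSet.

    ``table`` is indexed by ``probe_id`` and carries ``gene_symbol``,
    ``probe_class`` and (for positive spike-ins) ``spike_concentration``.
    Gene symbols are case-preserved; matching elsewhere is case-insensitive.
    Duplicate symbols with distinct probe ids are allowed -- the probe id is
    the key.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise PanelIOError(f"duplicate probe_id(s): {dups}")
        bad = set(t["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise PanelIOError(f"unknown probe class(es): {sorted(bad)}")

    def probes_of(self, probe_class: str) -> pd.Index:
        return self.table.index[self.table["probe_class"] == probe_class]

    @property
    def endogenous(self) -> pd.Index:
        return self.probes_of("endogenous")

    @property
    def housekeeping(self) -> pd.Index:
        return self.probes_of("housekeeping")

    @property
    def positive(self) -> pd.Index:
        return self.probes_of("positive")

    @property
    def negative(self) -> pd.Index:
        return self.probes_of("negative")

    def gene_symbol(self, probe_id: str) -> str:
        return str(self.table.loc[probe_id, "gene_symbol"])

    def require_normalizable(self) -> None:
        """A panel feeding the normalization chain needs all control classes."""
        for cls in ("positive", "negative", "housekeeping"):
            if len(self.probes_of(cls)) == 0:
                raise PanelIOError(f"panel has no {cls} probes")


@dataclass
class CountMatrix:
    """Probes x lanes counts plus lane metadata.

    ``values`` is indexed like ``panel.table`` (probe_id) with lane ids as
    columns.  ``lane_meta`` is indexed by lane_id with columns ``group`` and
    ``source_label``.  The raw state holds integers (stored as floats so the
    normalization chain needs no cast); all values are non-negative.
    """

    panel: ProbePanel
    values: pd.DataFrame
    state: str = "raw"
    lane_meta: pd.DataFrame | None = None
    audit: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise PanelIOError(f"unknown state {self.state!r}")
        if not self.values.index.equals(self.panel.table.index):
            # allow same set, different order -- but record it
            if set(self.values.index) != set(self.panel.table.index):
                raise PanelIOError("count rows do not match panel probes")
            self.values = self.values.loc[self.panel.table.index]
            self.audit.append("rows reordered to panel order")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise PanelIOError("non-numeric counts present")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            r, c = np.argwhere(~np.isfinite(arr) | (arr < 0))[0]
            raise PanelIOError(
                f"negative or non-finite count at probe "
                f"{self.values.index[r]!r}, lane {self.values.columns[c]!r}"
            )
        if self.state == "raw" and not np.allclose(arr, np.round(arr)):
            raise PanelIOError("raw state requires integer counts")
        self.values = self.values.astype(float)
        if self.lane_meta is not None:
            self._check_meta(self.lane_meta)

    def _check_meta(self, meta: pd.DataFrame) -> None:
        missing = [l for l in self.lanes if l not in meta.index]
        extra = [l for l in meta.index if l not in self.lanes]
        if missing or extra:
            raise PanelIOError(
                f"lane/metadata mismatch: lanes without metadata {missing}, "
                f"metadata without lanes {extra}"
            )

    @property
    def lanes(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> pd.Series:
        if self.lane_meta is None:
            raise PanelIOError("no lane metadata attached")
        return self.lane_meta["group"].loc[self.lanes]

    def lanes_in_group(self, group: str | Sequence[str]) -> list[str]:
        labels = [group] if isinstance(group, str) else list(group)
        g = self.groups()
        return [l for l in self.lanes if g[l] in labels]

    def subset_rows(self, probe_ids: Iterable[str]) -> pd.DataFrame:
        return self.values.loc[list(probe_ids)]

    def with_values(self, values: pd.DataFrame, state: str, note: str) -> "CountMatrix":
        """Functional update used by the normalization stages."""
        out = CountMatrix(
            panel=self.panel,
            values=values,
            state=state,
            lane_meta=self.lane_meta,
            audit=[*self.audit, note],
        )
        return out

    def attach_metadata(self, meta: pd.DataFrame) -> None:
        self._check_meta(meta)
        self.lane_meta = meta
        self.audit.append("lane metadata attached")


@dataclass
class LaneFactors:
    """Per-lane technical factors produced by the normalization chain.

    Columns: ``positive_factor`` (F_i), ``background`` (b_i),
    ``housekeeping_factor`` (K_i).  Filled in stage by stage; NaN until the
    corresponding stage has run.
    """

    table: pd.DataFrame

    @classmethod
    def empty(cls, lanes: Sequence[str]) -> "LaneFactors":
        return cls(
            pd.DataFrame(
                np.nan,
                index=pd.Index(lanes, name="lane_id"),
                columns=["positive_factor", "background", "housekeeping_factor"],
            )
        )

    def validate(self) -> None:
        t = self.table
        for col in ("positive_factor", "housekeeping_factor"):
            vals = t[col].dropna()
            if len(vals) and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
                raise PanelIOError(f"{col} must be finite and > 0")
        bg = t["background"].dropna()
        if len(bg) and np.any(bg < 0):
            raise PanelIOError("background must be >= 0")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _build_panel(probe_ids: Sequence[str], classes: Sequence[str],
                 symbols: Sequence[str] | None = None) -> ProbePanel:
    tab = pd.DataFrame(
        {
            "gene_symbol": list(symbols) if symbols is not None else list(probe_ids),
            "probe_class": list(classes),
            "spike_concentration": np.nan,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbePanel(tab)


def read_count_table(path: str | Path, format_dialect: str = "tsv_matrix",
                     panel: ProbePanel | None = None) -> CountMatrix:
    """Read a count table into a raw-state :class:`CountMatrix`.

    Dialects
    --------
    ``tsv_matrix`` / ``csv_matrix``
        First column ``probe_id``, optional ``gene_symbol`` and
        ``probe_class`` columns, remaining columns one lane each.  If the
        file has no probe_class column a companion ``panel`` must be given.
    ``rcc_dir``
        Directory of per-lane RCC-dialect text files; counts and classes are
        taken from each file's Code_Summary section.
    """
    path = Path(path)
    if not path.exists():
        raise PanelIOError(f"no such file or directory: {path}")
    if format_dialect == "rcc_dir":
        return _read_rcc_dir(path)
    if format_dialect not in ("tsv_matrix", "csv_matrix"):
        raise PanelIOError(f"unknown dialect {format_dialect!r}")
    sep = "\t" if format_dialect == "tsv_matrix" else ","
    state = "raw"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# state:"):
        declared = first.split(":", 1)[1].strip()
        if declared not in STATES:
            raise PanelIOError(f"{path}: unknown state {declared!r} in header")
        state = declared
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.empty:
        raise PanelIOError(f"{path}: empty count table")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "probe_id"
    symbols = df.pop("gene_symbol").tolist() if "gene_symbol" in df.columns else None
    if "probe_class" in df.columns:
        classes = df.pop("probe_class").tolist()
    elif panel is not None:
        classes = None
    else:
        raise PanelIOError(
            f"{path}: no 'probe_class' column and no companion panel given"
        )
    counts = df.apply(pd.to_numeric, errors="coerce")
    if counts.isna().any().any():
        r, c = np.argwhere(counts.isna().to_numpy())[0]
        raise PanelIOError(
            f"{path}: non-numeric count at probe {counts.index[r]!r}, "
            f"lane {counts.columns[c]!r} (value {df.iat[r, c]!r})"
        )
    if (counts.to_numpy() < 0).any():
        r, c = np.argwhere((counts < 0).to_numpy())[0]
        raise PanelIOError(
            f"{path}: negative count at probe {counts.index[r]!r}, "
            f"lane {counts.columns[c]!r} (value {counts.iat[r, c]})"
        )
    if classes is not None:
        panel = _build_panel(counts.index.tolist(), classes, symbols)
    assert panel is not None
    return CountMatrix(panel=panel, values=counts, state=state,
                       audit=[f"read {len(counts)} probes x {counts.shape[1]} lanes "
                              f"from {path.name} ({format_dialect})"])


def _read_rcc_dir(path: Path) -> CountMatrix:
    """Minimal RCC-dialect section parser.

    Only the ``<Code_Summary>`` block (CodeClass,Name,Accession,Count) and the
    lane id (from ``<Sample_Attributes>`` ID line, falling back to the file
    stem) are used; full vendor metadata is ignored.
    """
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".rcc")
    if not files:
        raise PanelIOError(f"{path}: no .rcc files found")
    lane_counts: dict[str, pd.Series] = {}
    panel_rows: pd.DataFrame | None = None
    for f in files:
        lane_id, rows = _parse_rcc(f)
        probe_ids = rows["Accession"].where(rows["Accession"] != "", rows["Name"])
        counts = pd.Series(rows["Count"].to_numpy(), index=probe_ids.to_numpy())
        tab = pd.DataFrame(
            {
                "gene_symbol": rows["Name"].to_numpy(),
                "probe_class": rows["CodeClass"].to_numpy(),
                "spike_concentration": np.nan,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
        if panel_rows is None:
            panel_rows = tab
        elif not panel_rows["probe_class"].equals(
            tab["probe_class"].reindex(panel_rows.index)
        ):
            raise PanelIOError(f"{f.name}: probe set differs from first lane")
        lane_counts[lane_id] = counts.reindex(panel_rows.index)
    assert panel_rows is not None
    panel = ProbePanel(panel_rows)
    values = pd.DataFrame(lane_counts)
    return CountMatrix(panel=panel, values=values, state="raw",
                       audit=[f"read {len(files)} RCC lanes from {path.name}"])


def _parse_rcc(f: Path) -> tuple[str, pd.DataFrame]:
    text = f.read_text()
    lane_id = f.stem
    m = re.search(r"<Sample_Attributes>(.*?)</Sample_Attributes>", text, re.S)
    if m:
        for line in m.group(1).strip().splitlines():
            k, _, v = line.partition(",")
            if k.strip() == "ID" and v.strip():
                lane_id = v.strip()
    m = re.search(r"<Code_Summary>(.*?)</Code_Summary>", text, re.S)
    if not m:
        raise PanelIOError(f"{f.name}: no Code_Summary section")
    lines = [l for l in m.group(1).strip().splitlines() if l.strip()]
    header = [h.strip() for h in lines[0].split(",")]
    for col in ("CodeClass", "Name", "Count"):
        if col not in header:
            raise PanelIOError(f"{f.name}: Code_Summary missing column {col!r}")
    rows = pd.DataFrame([l.split(",") for l in lines[1:]], columns=header)
    rows["CodeClass"] = rows["CodeClass"].str.strip().str.lower().map(
        lambda c: _RCC_CLASS_MAP.get(c, c)
    )
    bad = set(rows["CodeClass"]) - set(PROBE_CLASSES)
    if bad:
        raise PanelIOError(f"{f.name}: unknown CodeClass value(s) {sorted(bad)}")
    rows["Count"] = pd.to_numeric(rows["Count"], errors="coerce")
    if rows["Count"].isna().any():
        bad_row = rows.loc[rows["Count"].isna()].iloc[0]
        raise PanelIOError(f"{f.name}: non-numeric count for probe {bad_row['Name']!r}")
    if "Accession" not in rows.columns:
        rows["Accession"] = ""
    return lane_id, rows


def read_sample_metadata(path: str | Path,
                         lanes: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a lane_id/group TSV into a lane-metadata table.

    Unknown group labels are mapped to ``other`` with a warning.  If ``lanes``
    is given, the metadata must cover exactly those lanes.
    """
    path = Path(path)
    if not path.exists():
        raise PanelIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty or "lane_id" not in df.columns or "group" not in df.columns:
        raise PanelIOError(f"{path}: metadata needs non-empty lane_id and group columns")
    if df["lane_id"].duplicated().any():
        dups = df.loc[df["lane_id"].duplicated(), "lane_id"].tolist()
        raise PanelIOError(f"{path}: duplicate lane_id(s) {dups}")
    df = df.set_index("lane_id")
    unknown = ~df["group"].isin(GROUPS)
    if unknown.any():
        labels = sorted(df.loc[unknown, "group"].unique())
        logger.warning("unknown group label(s) %s mapped to 'other'", labels)
        df.loc[unknown, "group"] = "other"
    if "source_label" not in df.columns:
        df["source_label"] = df.index
    meta = df[["group", "source_label"]]
    if lanes is not None:
        missing = [l for l in lanes if l not in meta.index]
        extra = [l for l in meta.index if l not in lanes]
        if missing or extra:
            raise PanelIOError(
                f"{path}: lanes without metadata {missing}; "
                f"metadata without lanes {extra}"
            )
        meta = meta.loc[list(lanes)]
    return meta


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_count_matrix(cm: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = cm.values.copy()
    out.insert(0, "probe_class", cm.panel.table["probe_class"])
    out.insert(0, "gene_symbol", cm.panel.table["gene_symbol"])
    with open(path, "w") as fh:
        fh.write(f"# state: {cm.state}\n")
        out.to_csv(fh, sep="\t", float_format="%.17g")
    return path


def write_comparison_result(result, path: str | Path) -> Path:
    """Write a ComparisonResult table as TSV with a documenting header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "# per-gene differential expression: group means of normalized "
            "counts, fold change (mean_a/mean_b), log2 fold change, raw and "
            "BH-adjusted p, filter flags\n"
        )
        result.table.to_csv(fh, sep="\t", float_format="%.17g")
    return path


def write_results(objects: Mapping[str, object], out_dir: str | Path) -> dict[str, Path]:
    """Write a heterogeneous bundle of pipeline outputs.

    Dispatches on type: ComparisonResult -> TSV, SignatureSets -> per-set gene
    lists + JSON index, CountMatrix -> TSV, dict/dataclass -> JSON.
    Returns the mapping name -> written path (the SignatureSets entry points
    at its JSON index).
    """
    from .deconv_de import ComparisonResult, SignatureSets  # local: avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in objects.items():
        if isinstance(obj, ComparisonResult):
            written[name] = write_comparison_result(obj, out_dir / f"{name}.tsv")
        elif isinstance(obj, SignatureSets):
            index = {}
            for set_name, genes in obj.as_dict().items():
                p = out_dir / f"{name}.{set_name}.txt"
                p.write_text("".join(f"{g}\n" for g in sorted(genes)))
                index[set_name] = {"file": p.name, "n": len(genes)}
                written[f"{name}.{set_name}"] = p
            ip = out_dir / f"{name}.index.json"
            ip.write_text(json.dumps(index, indent=2, sort_keys=True) + "\n")
            written[name] = ip
        elif isinstance(obj, CountMatrix):
            written[name] = write_count_matrix(obj, out_dir / f"{name}.tsv")
        else:
            p = out_dir / f"{name}.json"
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                obj = dataclasses.asdict(obj)
            p.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                    default=_json_default) + "\n")
            written[name] = p
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="index")
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
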