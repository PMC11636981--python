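"""Readers and writers for the exchanged formats, config handling and run reports.

Conventions: genes are rows and samples are columns in every matrix; all
tables are UTF-8 and tab-separated with a header row (metadata may be CSV);
floats serialize with 10 significant digits so reruns with equal seeds are
byte-diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .simulate import STATES, SUBSTRATES, SimulationConfig

FLOAT_FMT = "%.10g"

METADATA_REQUIRED = ("sample", "treatment", *SUBSTRATES)


def read_counts(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV or MatrixMarket.

    MatrixMarket files must be accompanied by sibling ``<stem>.genes.txt``
    and ``<stem>.samples.txt`` name files (one ID per line).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)

        def _not_integer(v) -> bool:
            if isinstance(v, (int, np.integer)):
                return False
            try:
                return not float(v).is_integer()
            except (TypeError, ValueError):
                return True

        bad = df.map(_not_integer)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-integer cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        df = df.astype(np.int64)
    elif fmt == "mtx":
        mat = spio.mmread(path)
        genes = Path(path.parent / f"{path.stem}.genes.txt").read_text().split()
        samples = Path(path.parent / f"{path.stem}.samples.txt").read_text().split()
        arr = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if arr.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix dimensions {arr.shape} do not match name files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(arr.astype(np.int64), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate gene or sample IDs")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        counts.to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(counts.to_numpy()))
        (path.parent / f"{path.stem}.genes.txt").write_text("\n".join(counts.index) + "\n")
        (path.parent / f"{path.stem}.samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample table CSV/TSV with treatment and substrate-state columns."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    for sub in SUBSTRATES:
        bad = set(df[sub]) - set(STATES)
        if bad:
            raise ValueError(
                f"column {sub!r} contains unknown state(s) {sorted(bad)}; "
                f"allowed labels: {list(STATES)}"
            )
    return df


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    samples.to_csv(path, index=False)


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Gene -> functional categories from a two-column TSV (gene, category)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "category"):
        if col not in df.columns:
            raise ValueError(f"annotation is missing required column {col!r}")
    out: dict[str, list[str]] = {}
    for gene, cat in zip(df["gene"], df["category"]):
        out.setdefault(str(gene), []).append(str(cat))
    return out


def read_isotope_csv(path: str | Path):
    """IsotopeRecord list from CSV.

    Columns: worm_id, tissue, delta13c_lab, delta13c_nat_refs (semicolon-
    separated per-mille values), a_pct_water, dry_weight_g, hours,
    dw_ww_ratio, optional r_standard.
    """
    from . import tracer

    df = pd.read_csv(path)
    required = (
        "worm_id", "tissue", "delta13c_lab", "delta13c_nat_refs",
        "a_pct_water", "dry_weight_g", "hours", "dw_ww_ratio",
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"isotope CSV is missing required column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        refs = tuple(float(x) for x in str(row.delta13c_nat_refs).split(";"))
        records.append(
            tracer.IsotopeRecord(
                worm_id=str(row.worm_id),
                tissue=str(row.tissue),
                delta13c_lab=float(row.delta13c_lab),
                delta13c_nat_refs=refs,
                a_pct_water=float(row.a_pct_water),
                dry_weight_g=float(row.dry_weight_g),
                hours=float(row.hours),
                dw_ww_ratio=float(row.dw_ww_ratio),
                r_standard=float(getattr(row, "r_standard", tracer.R_VPDB)),
            )
        )
    return records


def read_uptake_csv(path: str | Path):
    """UptakeRecord list from CSV (substrate, c_in, c_out, flow_l_per_h,
    biomass_g, optional timestamp)."""
    from . import tracer

    df = pd.read_csv(path)
    required = ("substrate", "c_in", "c_out", "flow_l_per_h", "biomass_g")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"uptake CSV is missing required column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            tracer.UptakeRecord(
                substrate=str(row.substrate),
                c_in=None if pd.isna(row.c_in) else float(row.c_in),
                c_out=None if pd.isna(row.c_out) else float(row.c_out),
                flow_l_per_h=float(row.flow_l_per_h),
                biomass_g=float(row.biomass_g),
                timestamp=float(getattr(row, "timestamp", 0.0)),
            )
        )
    return records


def read_config(path: str | Path) -> dict:
    """YAML config: a ``simulation`` block (SimulationConfig fields) plus
    flat analysis parameters; unknown keys are preserved."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    sim_kwargs = dict(raw.get("simulation", {}))
    for key in ("module_sizes", "loading_range", "baseline_logmean_range",
                "libsize_range", "seed_set_modules"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    if "effect_sizes" in sim_kwargs:
        sim_kwargs["effect_sizes"] = tuple(dict(e) for e in sim_kwargs["effect_sizes"])
    cfg = SimulationConfig(**sim_kwargs)
    cfg.validate()
    out = dict(raw)
    out["simulation"] = cfg
    return out


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def write_config(config: dict, path: str | Path) -> None:
    out = dict(config)
    if isinstance(out.get("simulation"), SimulationConfig):
        out["simulation"] = config_to_dict(out["simulation"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Deterministic TSV writer (10-significant-digit floats)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def write_square_matrix(
    mat: np.ndarray, names: list[str], path: str | Path
) -> None:
    write_table(pd.DataFrame(mat, index=names, columns=names), path)


def write_edge_list(edge_table: pd.DataFrame, path: str | Path) -> None:
    write_table(edge_table, path, index=False)


def write_sif(edge_table: pd.DataFrame, path: str | Path, relation: str = "co") -> None:
    """Cytoscape SIF: 'source<TAB>relation<TAB>target' per edge."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"{r.source}\t{relation}\t{r.target}"
        for r in edge_table.itertuples(index=False)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    """Provenance of one pipeline run: config, seeds, timings, outputs."""

    seed: int
    config: dict = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    divergences: list[str] = field(
        default_factory=lambda: [
            "eBayes variance moderation uses standard moments estimation "
            "(no robust hyperparameter variant)",
            "module merge height 0.25 is a conventional default, not a "
            "reported value",
        ]
    )
    outputs: dict[str, str] = field(default_factory=dict)
    _t0: float = field(default_factory=time.monotonic, repr=False)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        s = int.from_bytes(h[:4], "big") % (2**31 - 1)
        self.stage_seeds[stage] = s
        return s

    def time_stage(self, stage: str) -> "_StageTimer":
        return _StageTimer(self, stage)

    def add_output(self, name: str, path: str | Path) -> None:
        self.outputs[name] = str(path)

    def to_json(self) -> str:
        d = {k: v for k, v in dataclasses.asdict(self).items() if not k.startswith("_")}
        if isinstance(d.get("config", {}).get("simulation"), SimulationConfig):
            d["config"]["simulation"] = config_to_dict(d["config"]["simulation"])
        return json.dumps(d, indent=1, sort_keys=True, default=_json_default)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(self.to_json() + "\n")


def _json_default(obj):
    if isinstance(obj, SimulationConfig):
        return config_to_dict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


class _StageTimer:
    def __init__(self, report: RunReport, stage: str):
        self.report, self.stage = report, stage

    def __enter__(self):
        self.start = time.monotonic()
        return self

    def __exit__(self, *exc):
        self.report.stage_seconds[self.stage] = round(time.monotonic() - self.start, 3)
        return False
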