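"""Cohort file formats, pipeline configuration and provenance.

All tabular I/O is plain comma-separated UTF-8 text with a header row;
files written by the pipeline begin with ``# key: value`` comment lines
carrying the package version and a hash of the configuration, so every
output is traceable to the thresholds that produced it.

Directory layout of a cohort::

    cohort.csv              subject/node table
    contours/<node_id>.csv  slice_index, vertex_index, x_mm, y_mm
    tic/<node_id>.csv       time_s, intensity, excluded

Contour files carry their slice spacing in a ``# spacing_mm:`` header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .morphometry import ContourStack
from .perfusion import TimeIntensityCurve
from .synthetic import SyntheticSubject

__all__ = [
    "PipelineConfig",
    "CohortTable",
    "load_cohort",
    "write_cohort",
    "read_contours",
    "write_contours",
    "read_tic",
    "write_tic",
    "write_table",
]

PACKAGE_VERSION = "0.1.0"

VALID_GROUPS = {"tumor_injected", "control_injected"}
VALID_SIDES = {"left", "right"}


@dataclass
class PipelineConfig:
    """Every threshold and default of the scoring pipeline in one place."""

    volume_ratio_threshold: float = 5.0
    roundness_cutoff: float = 2.0
    ttp_rel_margin: float = 0.2
    wir_rel_margin: float = 0.2
    arrival_k_sd: float = 3.0
    quality_gate_max_excluded: float = 0.4
    wir_source: str = "fitted"
    angle_tol_deg: float = 5.0
    densify_points: int = 256
    confidence: float = 0.95
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def config_hash(self) -> str:
        """Short stable digest of the configuration values."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class CohortTable:
    """Validated cohort manifest plus the directory it was loaded from."""

    table: pd.DataFrame
    root: Path


def _provenance_lines(config: PipelineConfig | None) -> str:
    lines = [f"# lnscore-version: {PACKAGE_VERSION}"]
    if config is not None:
        lines.append(f"# config-hash: {config.config_hash()}")
    return "\n".join(lines) + "\n"


def write_table(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write a CSV with provenance header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(config))
        df.to_csv(fh, index=False)


def _read_header_comments(path: Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("#").split(":", 1)
                out[k.strip()] = v.strip()
    return out


def write_contours(stack: ContourStack, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for si, poly in enumerate(stack.slices):
        for vi, (x, y) in enumerate(poly):
            rows.append((si, vi, x, y))
    df = pd.DataFrame(rows, columns=["slice_index", "vertex_index", "x_mm", "y_mm"])
    with open(path, "w") as fh:
        fh.write(f"# spacing_mm: {stack.spacing_mm!r}\n")
        df.to_csv(fh, index=False)


def read_contours(path: str | Path, node_id: str = "") -> ContourStack:
    path = Path(path)
    meta = _read_header_comments(path)
    if "spacing_mm" not in meta:
        raise SchemaError(f"{path}: missing '# spacing_mm:' header")
    df = pd.read_csv(path, comment="#")
    slices = [
        g.sort_values("vertex_index")[["x_mm", "y_mm"]].to_numpy()
        for _, g in df.sort_values(["slice_index", "vertex_index"]).groupby(
            "slice_index", sort=True
        )
    ]
    return ContourStack(
        slices=slices,
        spacing_mm=float(meta["spacing_mm"]),
        node_id=node_id or path.stem,
    )


def write_tic(tic: TimeIntensityCurve, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_s": tic.time_s,
            "intensity": tic.intensity,
            "excluded": tic.excluded.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_tic(path: str | Path, node_id: str = "") -> TimeIntensityCurve:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    return TimeIntensityCurve(
        time_s=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        excluded=df["excluded"].to_numpy().astype(bool),
        node_id=node_id or path.stem,
    )


def write_cohort(
    subjects: list[SyntheticSubject],
    outdir: str | Path,
    spec_dict: dict | None = None,
) -> Path:
    """Write a generated cohort to the standard directory layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        for node, path_pos in ((s.left, s.pathology_positive_left),
                               (s.right, s.pathology_positive_right)):
            contour_path = f"contours/{node.node_id}.csv"
            write_contours(node.contours, outdir / contour_path)
            tic_path = ""
            if node.tic is not None:
                tic_path = f"tic/{node.node_id}.csv"
                write_tic(node.tic, outdir / tic_path)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "side": node.side,
                    "node_id": node.node_id,
                    "hilum_visible": int(node.hilum_visible),
                    "pathology_positive": int(path_pos),
                    "contour_path": contour_path,
                    "tic_path": tic_path,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    if spec_dict is not None:
        (outdir / "cohort_spec.yaml").write_text(
            yaml.safe_dump(spec_dict, sort_keys=True)
        )
    return outdir


REQUIRED_COHORT_COLUMNS = [
    "subject_id", "group", "side", "node_id",
    "hilum_visible", "pathology_positive", "contour_path", "tic_path",
]


def load_cohort(path: str | Path) -> CohortTable:
    """Load and validate a cohort directory (or its cohort.csv directly).

    Raises :class:`SchemaError` naming the offending row for duplicate
    (subject, side) pairs, unknown groups or sides, and missing files.
    """
    path = Path(path)
    csv_path = path / "cohort.csv" if path.is_dir() else path
    root = csv_path.parent
    if not csv_path.exists():
        raise SchemaError(f"no cohort table at {csv_path}")
    df = pd.read_csv(csv_path, comment="#", dtype={"tic_path": str}, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{csv_path}: missing columns {missing_cols}")
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        where = f"{csv_path} row {i} (node {row['node_id']!r})"
        if row["group"] not in VALID_GROUPS:
            raise SchemaError(f"{where}: unknown group {row['group']!r}")
        if row["side"] not in VALID_SIDES:
            raise SchemaError(f"{where}: unknown side {row['side']!r}")
        key = (row["subject_id"], row["side"])
        if key in seen:
            raise SchemaError(f"{where}: duplicate subject/side pair {key}")
        seen.add(key)
        if not (root / row["contour_path"]).exists():
            raise SchemaError(f"{where}: contour file {row['contour_path']!r} missing")
        if row["tic_path"] and not (root / row["tic_path"]).exists():
            raise SchemaError(f"{where}: TIC file {row['tic_path']!r} missing")
    return CohortTable(table=df, root=root)
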