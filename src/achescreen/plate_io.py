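"""Tabular IO for kinetic plates, layouts and result tables, plus run config.

The kinetic dialect is long-form CSV, UTF-8, period decimals, one row per
(well, timepoint):

    well,sample,role,dose,replicate,time_min,phase,absorbance

``phase`` is ``pre`` (before enzyme addition) or ``post`` (the single read
after addition).  Concentrations are µg/mL throughout.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("achescreen")

ROLES = ("sample", "negative_control", "positive_control", "blank")

KINETIC_COLUMNS = [
    "well",
    "sample",
    "role",
    "dose",
    "replicate",
    "time_min",
    "phase",
    "absorbance",
]

PRE_TIMES = (0.0, 3.0, 6.0, 9.0)


@dataclass(frozen=True)
class Well:
    """One well of a plate layout."""

    well: str
    sample: str
    role: str
    dose: float
    replicate: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"well {self.well}: unknown role {self.role!r}")
        if self.role == "sample" and not self.dose >= 0:
            raise ValueError(f"well {self.well}: sample wells need dose >= 0")


@dataclass(frozen=True)
class PlateLayout:
    wells: tuple[Well, ...]

    def __init__(self, wells) -> None:
        object.__setattr__(self, "wells", tuple(wells))
        ids = [w.well for w in self.wells]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate well id(s) in layout: {sorted(dupes)}")

    def by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]


@dataclass(frozen=True)
class KineticRecord:
    """One well's absorbance trace: four pre-enzyme reads and one post read."""

    well: str
    pre_reads: tuple[tuple[float, float], ...]
    post_read: tuple[float, float]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.pre_reads]
        if len(self.pre_reads) != len(PRE_TIMES) or tuple(times) != PRE_TIMES:
            raise ValueError(
                f"well {self.well}: pre-enzyme reads must be at minutes {PRE_TIMES}, got {times}"
            )
        if not self.post_read[0] > PRE_TIMES[-1]:
            raise ValueError(
                f"well {self.well}: post-enzyme read time {self.post_read[0]} "
                f"must exceed {PRE_TIMES[-1]} min"
            )


@dataclass
class KineticPlate:
    """Parsed kinetic plate: layout, per-well records, and wells dropped by QC."""

    layout: PlateLayout
    records: dict[str, KineticRecord]
    flagged_wells: dict[str, str] = field(default_factory=dict)


def write_kinetic_csv(kinetic: pd.DataFrame, path: str | Path) -> None:
    """Write a long-form kinetic table in the documented dialect.

    Absorbances are written at full (shortest-repr) precision so the table
    round-trips exactly; identical inputs yield identical bytes.
    """
    df = kinetic[KINETIC_COLUMNS]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def read_kinetic_csv(path: str | Path) -> KineticPlate:
    """Parse a kinetic CSV into a :class:`KineticPlate`.

    Wells with unparseable absorbance values (e.g. ``NA``) are flagged and
    dropped from ``records``; structural problems — missing columns or a
    duplicated (well, phase, time) row — are hard errors naming the culprit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"well": str, "sample": str, "role": str, "phase": str})
    return plate_from_frame(df, source=path.name)


def plate_from_frame(df: pd.DataFrame, source: str = "<frame>") -> KineticPlate:
    """Build a :class:`KineticPlate` from an in-memory long-form table.

    Shared by :func:`read_kinetic_csv` and the synthetic generator so that
    simulated plates can enter the reduction without a disk round trip.
    """
    missing = [c for c in KINETIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")

    dup = df.duplicated(subset=["well", "phase", "time_min"], keep=False)
    if dup.any():
        bad = sorted(df.loc[dup, "well"].unique())
        raise ValueError(f"{source}: duplicated reads for well(s) {bad}")

    df["absorbance"] = pd.to_numeric(df["absorbance"], errors="coerce")

    wells: list[Well] = []
    records: dict[str, KineticRecord] = {}
    flagged: dict[str, str] = {}
    for well_id, grp in df.groupby("well", sort=False):
        meta = grp.iloc[0]
        wells.append(
            Well(
                well=str(well_id),
                sample=str(meta["sample"]),
                role=str(meta["role"]),
                dose=float(meta["dose"]),
                replicate=int(meta["replicate"]),
            )
        )
        if meta["role"] == "blank":
            continue
        if grp["absorbance"].isna().any():
            lines = [str(i + 2) for i in grp.index[grp["absorbance"].isna()]]
            flagged[str(well_id)] = f"non-numeric absorbance at line(s) {', '.join(lines)}"
            log.warning("well %s flagged: %s", well_id, flagged[str(well_id)])
            continue
        pre = grp[grp["phase"] == "pre"].sort_values("time_min")
        post = grp[grp["phase"] == "post"]
        if len(post) != 1:
            raise ValueError(f"{source}: well {well_id} needs exactly one post-enzyme read")
        records[str(well_id)] = KineticRecord(
            well=str(well_id),
            pre_reads=tuple(zip(pre["time_min"].astype(float), pre["absorbance"].astype(float))),
            post_read=(float(post["time_min"].iloc[0]), float(post["absorbance"].iloc[0])),
        )
    return KineticPlate(layout=PlateLayout(wells), records=records, flagged_wells=flagged)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write result tables as ``<name>.csv`` with deterministic bytes.

    Column order is preserved, floats use up to six significant figures, and
    rewriting identical inputs yields identical checksums.  Empty tables
    produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise NotADirectoryError(out_dir)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")
        written[name] = path
        log.info("wrote %s (%d rows, sha1 %s)", path, len(df), checksum(path)[:10])
    return written


def checksum(path: str | Path) -> str:
    return hashlib.sha1(Path(path).read_bytes()).hexdigest()


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Load a YAML run config and apply CLI overrides (CLI wins).

    The effective parameter set is logged so every run echoes what it used.
    """
    config: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    for key, val in (overrides or {}).items():
        if val is not None:
            config[key] = val
    log.info("effective config: %s", config)
    return config


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile, encoding="utf-8"))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
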