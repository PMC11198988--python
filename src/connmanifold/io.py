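"""Shared data model, delimited-text readers/writers, and run configuration.

Tab-separated text is the canonical interchange format for every table the
pipeline produces (time series, parcellation metadata, covariance matrices,
eccentricity and contrast tables). Values are serialized with 17 significant
digits so that a write/read round trip is bit-exact for doubles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("connmanifold")

#: decimal precision guaranteeing float64 round trips through text
FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A delimited input file violated its format contract."""


class ValidationError(ValueError):
    """An input parsed but failed a semantic invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RegionTimeSeries:
    """Region-by-volume activity matrix for one scan.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_volumes)
        Extracted regional activity (arbitrary units).
    region_ids : sequence of str
        Unique region identifiers, one per row.
    tr : float
        Repetition time between volumes, in seconds.
    """

    values: np.ndarray
    region_ids: list[str]
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        if self.values.ndim != 2:
            raise ValidationError("time series must be a 2-D matrix")
        if self.values.shape[1] < 2:
            raise ValidationError("time series needs at least 2 volumes")
        if len(self.region_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.region_ids)} region ids for {self.values.shape[0]} rows"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValidationError("region ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("time series contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class ParcellationMeta:
    """Per-region metadata: hemisphere, network labels and spherical centroid.

    Centroids live on the unit sphere (the analog of parcel centers on a
    spherical cortical mesh) and drive the spin-test rotations. Subcortical
    regions carry centroids but are never rotated.
    """

    region_ids: list[str]
    hemisphere: list[str]  # 'left' | 'right' | 'subcortical'
    network7: list[str]
    network17: list[str]
    centroids: np.ndarray  # (n_regions, 3), unit rows

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise ValidationError("duplicate region_id in parcellation")
        for name, col in (
            ("hemisphere", self.hemisphere),
            ("network7", self.network7),
            ("network17", self.network17),
        ):
            if len(col) != n:
                raise ValidationError(f"{name} length != number of regions")
        bad = set(self.hemisphere) - {"left", "right", "subcortical"}
        if bad:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad)}")
        if self.centroids.shape != (n, 3):
            raise ValidationError("centroids must be (n_regions, 3)")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("centroids must be unit vectors (|norm-1| <= 1e-6)")
        # renormalize tiny drift so downstream code can rely on exact unit norm
        self.centroids = self.centroids / norms[:, None]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def is_cortical(self) -> np.ndarray:
        return np.array([h != "subcortical" for h in self.hemisphere])

    def network_labels(self, level: int = 17) -> np.ndarray:
        if level == 7:
            return np.asarray(self.network7)
        if level == 17:
            return np.asarray(self.network17)
        raise ValueError("network level must be 7 or 17")


@dataclass
class RunConfig:
    """Numeric knobs for a full pipeline run, loadable from YAML."""

    seed: int = 0
    epoch_length: int = 210
    discard_leading: int = 6
    highpass_s: float = 128.0
    lowpass_s: float = 100.0
    manifold_dim: int = 3
    threshold_fraction: float = 0.10
    n_spins: int = 1000
    q: float = 0.05
    centering_tol: float = 1e-10
    centering_max_iter: int = 200
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "epoch_length",
            "highpass_s",
            "lowpass_s",
            "manifold_dim",
            "n_spins",
            "q",
            "centering_tol",
            "centering_max_iter",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name} must be positive")
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValidationError("threshold_fraction must be in (0, 1]")
        if self.discard_leading < 0:
            raise ValidationError("discard_leading must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_timeseries(path: str | Path, tr: float = 2.0) -> RegionTimeSeries:
    """Read a volumes-by-regions TSV (region-id header row) as a RegionTimeSeries.

    The file stores one volume per line; the returned matrix is transposed to
    regions x volumes with region ids in header order.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        ids = header.split("\t")
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(ids):
                raise ParseError(
                    f"{path}: line {lineno} has {len(cells)} cells, expected {len(ids)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 volumes, found {len(rows)}")
    return RegionTimeSeries(values=np.array(rows).T, region_ids=ids, tr=tr)


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    """Write a RegionTimeSeries as a volumes-by-regions TSV (inverse of read)."""
    _write_matrix(ts.values.T, ts.region_ids, Path(path))


PARCELLATION_COLUMNS = ["region_id", "hemisphere", "network7", "network17", "x", "y", "z"]


def read_parcellation(path: str | Path) -> ParcellationMeta:
    """Read a parcel metadata table (region_id, hemisphere, networks, centroid)."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    missing = set(PARCELLATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate region_id {dup!r}")
    return ParcellationMeta(
        region_ids=df["region_id"].tolist(),
        hemisphere=df["hemisphere"].tolist(),
        network7=df["network7"].tolist(),
        network17=df["network17"].tolist(),
        centroids=df[["x", "y", "z"]].to_numpy(float),
    )


def write_parcellation(meta: ParcellationMeta, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_id": meta.region_ids,
            "hemisphere": meta.hemisphere,
            "network7": meta.network7,
            "network17": meta.network17,
            "x": meta.centroids[:, 0],
            "y": meta.centroids[:, 1],
            "z": meta.centroids[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_trials(path: str | Path):
    """Read per-trial (trial, t, x, y) samples into a TrialSet.

    Coordinates are millimetres with the origin at the start position and +y
    toward the target; timestamps are seconds from trial onset and must be
    strictly increasing within a trial.
    """
    from .behavior import Trajectory, TrialSet  # deferred: avoid import cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        logger.warning("%s: empty trial file, returning empty TrialSet", path)
        return TrialSet(trajectories=[])
    missing = {"trial", "t", "x", "y"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    trajectories = []
    for trial, grp in df.groupby("trial", sort=True):
        t = grp["t"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{path}: non-monotone timestamps in trial {trial}")
        trajectories.append(
            Trajectory(t=t, x=grp["x"].to_numpy(float), y=grp["y"].to_numpy(float), trial=int(trial))
        )
    return TrialSet(trajectories=trajectories)


def write_trials(trial_set, path: str | Path) -> None:
    frames = []
    for traj in trial_set.trajectories:
        frames.append(
            pd.DataFrame({"trial": traj.trial, "t": traj.t, "x": traj.x, "y": traj.y})
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["trial", "t", "x", "y"])
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square or rectangular labeled matrix TSV (header = column ids)."""
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
    values = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    return values, ids


def _write_matrix(values: np.ndarray, col_ids: Sequence[str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(str(c) for c in col_ids) + "\n")
        np.savetxt(fh, np.atleast_2d(values), fmt=FLOAT_FMT, delimiter="\t")


def write_matrix(values: np.ndarray, col_ids: Sequence[str], path: str | Path) -> None:
    _write_matrix(np.asarray(values, float), col_ids, Path(path))


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    report: Mapping,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write named result tables as TSV plus a JSON run summary.

    Column order within each table is preserved as given (deterministic);
    the report (seeds, config echo, warnings) is written to ``run_summary.json``.
    Returns the mapping from table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
        written[name] = p
    summary_path = out_dir / "run_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    written["run_summary"] = summary_path
    return written
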