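"""Readers/writers for long-format transition data and run configuration.

Canonical on-disk format: one CSV row per individual with columns
``id, origin, event, destination, time_kind, k_star, k1, k2`` followed by
covariate columns.  ``origin`` and ``destination`` are 0-based state
indices; times are nonnegative integers in model units (one row per
individual suffices for star topologies).

Datasets whose times are recorded on a calendar scale (e.g. survival days
in registry data) must be discretized upstream into integer model units;
the choice of discretization step is the user's and should be logged with
the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import EXACT, INTERVAL, Observation

__all__ = [
    "REQUIRED_COLUMNS",
    "CovariateEncoding",
    "write_dataset",
    "read_dataset",
    "observations_from_frame",
    "observations_to_frame",
    "split_stratified",
    "load_config",
]

REQUIRED_COLUMNS = ["id", "origin", "event", "destination", "time_kind", "k_star", "k1", "k2"]


@dataclass(frozen=True)
class CovariateEncoding:
    """Per-covariate category-to-value maps.

    Two-category covariates map onto {0, 1}; three-category covariates
    onto {0, 0.5, 1}.  :meth:`from_categories` builds the equally spaced
    map from an ordered category list.
    """

    maps: Dict[str, Dict[object, float]]

    def __post_init__(self):
        for col, mapping in self.maps.items():
            for cat, val in mapping.items():
                if not (0.0 <= val <= 1.0):
                    raise ValueError(
                        f"encoded value {val} for {col}={cat!r} outside [0,1]")

    @classmethod
    def from_categories(cls, categories: Dict[str, Sequence]) -> "CovariateEncoding":
        maps = {}
        for col, cats in categories.items():
            cats = list(cats)
            if len(cats) < 2:
                raise ValueError(f"covariate {col!r} needs >= 2 categories")
            step = 1.0 / (len(cats) - 1)
            maps[col] = {c: i * step for i, c in enumerate(cats)}
        return cls(maps)

    def encode(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col, mapping in self.maps.items():
            if col not in out:
                raise ValueError(f"missing covariate column {col!r}")
            unknown = set(out[col].unique()) - set(mapping)
            if unknown:
                raise ValueError(f"unknown categories {unknown!r} in column {col!r}")
            out[col] = out[col].map(mapping).astype(float)
        return out


def observations_to_frame(observations: Sequence[Observation],
                          covariate_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    d = observations[0].covariates.size
    names = list(covariate_names) if covariate_names else [f"x{j+1}" for j in range(d)]
    rows = []
    for o in observations:
        row = {
            "id": o.individual_id,
            "origin": o.origin_state,
            "event": o.event,
            "destination": "" if o.destination_state is None else o.destination_state,
            "time_kind": o.time_kind,
            "k_star": "" if o.k_star is None else o.k_star,
            "k1": "" if o.k1 is None else o.k1,
            "k2": "" if o.k2 is None else o.k2,
        }
        row.update(dict(zip(names, o.covariates)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(observations: Sequence[Observation], path,
                  covariate_names: Optional[Sequence[str]] = None) -> None:
    observations_to_frame(observations, covariate_names).to_csv(path, index=False)


def _opt_int(value, line: int, name: str):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    v = float(value)
    if v != int(v) or v < 0:
        raise ValueError(f"line {line}: column {name!r} must be a nonnegative integer, got {value!r}")
    return int(v)


def observations_from_frame(frame: pd.DataFrame,
                            covariate_columns: Sequence[str]) -> List[Observation]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    missing = [c for c in covariate_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    obs = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        line = pos + 2  # header is line 1
        try:
            dest = _opt_int(row["destination"], line, "destination")
            obs.append(Observation(
                individual_id=row["id"],
                origin_state=int(row["origin"]),
                event=int(row["event"]),
                destination_state=dest,
                time_kind=str(row["time_kind"]),
                k_star=_opt_int(row["k_star"], line, "k_star"),
                k1=_opt_int(row["k1"], line, "k1"),
                k2=_opt_int(row["k2"], line, "k2"),
                covariates=np.asarray([row[c] for c in covariate_columns], dtype=float),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid record at line {line}: {exc}") from exc
    return obs


def read_dataset(path, covariate_columns: Optional[Sequence[str]] = None,
                 encoding: Optional[CovariateEncoding] = None) -> List[Observation]:
    """Read and validate a long-format CSV into observations.

    Covariate columns default to every column not in the required set;
    categorical covariates are encoded through ``encoding`` first.
    """
    frame = pd.read_csv(path)
    if covariate_columns is None:
        covariate_columns = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
    if encoding is not None:
        frame = encoding.encode(frame)
    return observations_from_frame(frame, covariate_columns)


def split_stratified(observations: Sequence[Observation], fraction: float,
                     seed: int = 0) -> Tuple[List[Observation], List[Observation]]:
    """Per-stratum random train/validation split.

    Strata are the observed destination state, or "censored".  Each
    stratum is split at ``fraction`` (rounded) into train vs. validation
    so every transition is represented in similar proportions in both.
    Strata with fewer than two members go to the training split.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    strata: Dict[object, List[int]] = {}
    for i, o in enumerate(observations):
        key = o.destination_state if o.event else "censored"
        strata.setdefault(key, []).append(i)
    train_idx: List[int] = []
    valid_idx: List[int] = []
    for key in sorted(strata, key=str):
        members = np.array(strata[key])
        if len(members) < 2:
            train_idx.extend(members.tolist())
            continue
        perm = rng.permutation(len(members))
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.extend(members[perm[:n_train]].tolist())
        valid_idx.extend(members[perm[n_train:]].tolist())
    train_idx.sort()
    valid_idx.sort()
    return ([observations[i] for i in train_idx],
            [observations[i] for i in valid_idx])


def load_config(path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return cfg
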