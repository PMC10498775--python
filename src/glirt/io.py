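"""Response-matrix readers/writers, run configuration, and ICC curve export.

Response files are comma-delimited: a header row of item ids, a first column
of person ids, and cells in {0, 1} or a configurable set of missing codes
(default {6, 9}, the "Not Reached" / "No Response" convention of PISA
released files).  Two missing-data policies are supported: dropping every
person whose row contains any missing code (the default), or keeping such
persons and skipping the missing cells in the likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import ModelSpec, ItemParams, icc

__all__ = [
    "ResponseMatrix",
    "read_response_matrix",
    "write_response_matrix",
    "export_icc_curves",
    "RunConfig",
    "load_run_config",
]

DEFAULT_MISSING_CODES = frozenset({6, 9})


@dataclass
class ResponseMatrix:
    """Persons x items dichotomous responses with an explicit missing mask.

    ``values`` holds 0/1 (missing cells hold 0 and are flagged in ``mask``,
    True = missing).
    """

    values: np.ndarray
    mask: np.ndarray
    person_ids: Sequence
    item_ids: Sequence

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 2:
            raise ValueError("response matrix must be 2-D")
        n, j = self.values.shape
        if len(self.person_ids) != n or len(self.item_ids) != j:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.person_ids)) != n or len(set(self.item_ids)) != j:
            raise ValueError("ids must be unique")
        obs = self.values[~self.mask]
        if obs.size == 0:
            raise ValueError("response matrix has no observed cells")
        if not np.isin(obs, (0, 1)).all():
            raise ValueError("observed cells must be 0/1")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int((~self.mask).sum())

    @classmethod
    def from_values(cls, values, person_ids=None, item_ids=None,
                    mask=None) -> "ResponseMatrix":
        values = np.asarray(values)
        n, j = values.shape
        if person_ids is None:
            person_ids = [f"p{i + 1}" for i in range(n)]
        if item_ids is None:
            item_ids = [f"item{k + 1}" for k in range(j)]
        if mask is None:
            mask = np.zeros_like(values, dtype=bool)
        return cls(values, mask, list(person_ids), list(item_ids))

    def to_frame(self, missing_code: int = 9) -> pd.DataFrame:
        coded = getattr(self, "_coded_values", None)
        if coded is not None:
            vals = np.asarray(coded, dtype=int)
        else:
            vals = self.values.astype(int).copy()
            vals[self.mask] = missing_code
        return pd.DataFrame(vals, index=pd.Index(self.person_ids, name="person"),
                            columns=list(self.item_ids))


def read_response_matrix(
    path,
    missing_codes: Iterable[int] = DEFAULT_MISSING_CODES,
    exclusion: str = "drop_person_with_any_missing",
) -> ResponseMatrix:
    """Read a persons x items CSV of 0/1 responses with missing codes.

    ``exclusion`` is ``"drop_person_with_any_missing"`` (remove every person
    whose row contains a missing code) or ``"keep"`` (flag those cells as
    missing so the likelihood skips them).  Any cell outside
    {0, 1} | missing_codes is a hard error naming the row and column.
    """
    if exclusion not in ("drop_person_with_any_missing", "keep"):
        raise ValueError(f"unknown exclusion policy {exclusion!r}")
    codes = set(int(c) for c in missing_codes)
    if codes & {0, 1}:
        raise ValueError("missing codes may not overlap response values {0, 1}")
    df = pd.read_csv(path, index_col=0)
    raw = df.to_numpy()
    try:
        raw = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    valid = {0, 1} | codes
    intvals = np.full(raw.shape, -1, dtype=int)
    ok = np.isfinite(raw) & (raw == np.round(raw))
    intvals[ok] = raw[ok].astype(int)
    bad = ~(ok & np.isin(intvals, sorted(valid)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid cell value {raw[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}: expected 0/1 or one of {sorted(codes)}"
        )
    mask = np.isin(intvals, sorted(codes)) if codes else np.zeros(raw.shape, bool)
    if exclusion == "drop_person_with_any_missing":
        keep = ~mask.any(axis=1)
        intvals = intvals[keep]
        mask = np.zeros_like(intvals, dtype=bool)
        persons = list(df.index[keep])
    else:
        persons = list(df.index)
    vals = np.where(mask, 0, intvals)
    return ResponseMatrix(vals, mask, persons, list(df.columns))


def write_response_matrix(rm: ResponseMatrix, path, missing_code: int = 9) -> None:
    rm.to_frame(missing_code=missing_code).to_csv(path)


def export_icc_curves(model: ModelSpec, items: Sequence[ItemParams],
                      theta_grid) -> pd.DataFrame:
    """Long-format table (item, theta, prob) of ICC values on a theta grid."""
    theta_grid = np.asarray(theta_grid, dtype=float)
    if not np.all(np.isfinite(theta_grid)):
        raise ValueError("theta grid must be finite")
    rows = []
    for k, item in enumerate(items):
        p = np.atleast_1d(icc(model, theta_grid, item))
        rows.append(pd.DataFrame(
            {"item": k + 1, "theta": theta_grid, "prob": p}
        ))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_SCHEMA = {
    "family": str,
    "n_persons": int,
    "n_items": int,
    "n_reps": int,
    "n_chains": int,
    "n_iterations": int,
    "n_burnin": int,
    "seed": int,
    "missing_codes": list,
    "exclusion": str,
    "out_dir": str,
    "data": str,
    "fitted_families": list,
}

_DEFAULTS = {
    "family": "rasch",
    "n_persons": 1000,
    "n_items": 20,
    "n_reps": 1,
    "n_chains": 4,
    "n_iterations": 3000,
    "n_burnin": 2000,
    "seed": 1,
    "missing_codes": [6, 9],
    "exclusion": "drop_person_with_any_missing",
    "out_dir": "glirt_out",
    "data": "",
    "fitted_families": ["glogit_free", "rasch", "pno_glogit", "cllm_glogit"],
}


@dataclass
class RunConfig:
    """Validated run settings shared by the CLI subcommands."""

    family: str = "rasch"
    n_persons: int = 1000
    n_items: int = 20
    n_reps: int = 1
    n_chains: int = 4
    n_iterations: int = 3000
    n_burnin: int = 2000
    seed: int = 1
    missing_codes: list = field(default_factory=lambda: [6, 9])
    exclusion: str = "drop_person_with_any_missing"
    out_dir: str = "glirt_out"
    data: str = ""
    fitted_families: list = field(
        default_factory=lambda: list(_DEFAULTS["fitted_families"]))

    def __post_init__(self):
        errors = []
        for key, typ in _SCHEMA.items():
            val = getattr(self, key)
            if not isinstance(val, typ) or isinstance(val, bool):
                errors.append(f"{key}: expected {typ.__name__}, got {val!r}")
        for key in ("n_persons", "n_items", "n_reps", "n_chains", "n_iterations"):
            if isinstance(getattr(self, key), int) and getattr(self, key) < 1:
                errors.append(f"{key}: must be >= 1")
        if isinstance(self.n_burnin, int) and isinstance(self.n_iterations, int):
            if not 0 <= self.n_burnin < self.n_iterations:
                errors.append("n_burnin: must satisfy 0 <= n_burnin < n_iterations")
        if errors:
            raise ValueError("invalid run config: " + "; ".join(errors))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def load_run_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides."""
    settings = dict(_DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        settings.update(loaded)
    if overrides:
        settings.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**settings)
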