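"""Result CSV round-tripping and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .dynamics import STAGES, SimulationResults

__all__ = ["write_result", "read_result", "RunManifest"]

#: Fixed column order of a result CSV (after the leading ``date`` column).
RESULT_COLUMNS = list(STAGES) + ["E_l", "A_total", "A_h", "favorable"]


def write_result(result: SimulationResults, path: str | Path) -> None:
    """Write the reported (post-spin-up) daily trajectory to CSV at full
    float precision, one row per day."""
    df = result.data[RESULT_COLUMNS].copy()
    df["favorable"] = df["favorable"].astype(int)
    df.to_csv(path, float_format="%.17g")


def read_result(path: str | Path) -> SimulationResults:
    """Read a result CSV back into a :class:`SimulationResults` (without the
    originating parameters/config)."""
    try:
        df = pd.read_csv(path, parse_dates=["date"], index_col="date",
                         float_precision="round_trip")
    except Exception as exc:  # pandas reports the offending line number
        raise ValueError(f"{path}: cannot parse result CSV: {exc}") from exc
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty trajectory")
    df = df[RESULT_COLUMNS]
    df["favorable"] = df["favorable"].astype(bool)
    return SimulationResults(df, params=None, config=None)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run a CLI result bit-identically: the exact
    argument vector, the parameter values used, the run configuration, input
    file checksums, package version and seed (if any)."""

    command: list[str]
    params: dict | None = None
    config: dict | None = None
    inputs: dict = dataclasses.field(default_factory=dict)
    seed: int | None = None
    version: str = __version__

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def write(self, out_path: str | Path) -> Path:
        """Write the manifest next to *out_path* as ``<out>.manifest.json``."""
        target = Path(str(out_path) + ".manifest.json")
        with open(target, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        return target

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
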