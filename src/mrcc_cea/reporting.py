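"""Result serialization and run manifests.

Every CLI run writes its tables (CSV, full precision), a JSON report, a
rounded human-readable summary, and a ``manifest.json`` recording the
configuration digest, seed, package version and subcommand so identical
(config, seed) pairs can be recognised as identical runs.  Output file
names are deterministic; only the manifest timestamp differs between
reruns.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_results"]

_CSV_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one output directory."""

    config_digest: str
    subcommand: str
    seed: int | None = None
    package_version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        stamp = self.timestamp or datetime.datetime.now(datetime.timezone.utc).isoformat()
        return {
            "config_digest": self.config_digest,
            "subcommand": self.subcommand,
            "seed": self.seed,
            "package_version": self.package_version,
            "timestamp": stamp,
        }


def _round_floats(obj, ndigits: int = 4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_results(
    out_dir: str | Path,
    manifest: RunManifest,
    tables: Mapping[str, pd.DataFrame] | None = None,
    report: Mapping | None = None,
) -> list[Path]:
    """Write tables as CSV and the report as JSON into ``out_dir``.

    The report is written twice: ``report.json`` at full precision and
    ``summary.json`` rounded for reading.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame in (tables or {}).items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
        written.append(path)
    if report is not None:
        path = out / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(path)
        path = out / "summary.json"
        path.write_text(json.dumps(_round_floats(report), indent=2, sort_keys=True) + "\n")
        written.append(path)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
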