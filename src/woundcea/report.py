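"""Tabular exports and run manifests.

All exports are locale-independent CSV (UTF-8, comma delimiter, period
decimal separator) written at full floating precision; base-case exports
additionally carry report-precision columns (2 dp costs, 4 dp rates).
Every output directory receives exactly one ``manifest.json`` recording how
its contents were produced, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .cea import BaseCaseResult, OwsaResult
from .psa import CeacCurve, PsaResult

__all__ = [
    "export_base_case",
    "export_owsa",
    "export_psa_samples",
    "export_ce_plane",
    "export_ceac",
    "write_manifest",
]


def _package_version() -> str:
    try:
        return version("woundcea")
    except PackageNotFoundError:
        return "unknown"


def export_base_case(result: BaseCaseResult, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False)
    return path


def export_owsa(result: OwsaResult, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False)
    return path


def export_psa_samples(psa: PsaResult, path: str | Path) -> Path:
    path = Path(path)
    psa.frame.to_csv(path, index=False)
    return path


def export_ce_plane(psa: PsaResult, path: str | Path) -> Path:
    path = Path(path)
    psa.ce_plane().to_csv(path, index=False)
    return path


def export_ceac(curve: CeacCurve, path: str | Path) -> Path:
    path = Path(path)
    curve.to_frame().to_csv(path, index=False)
    return path


def write_manifest(
    outdir: str | Path,
    subcommand: str,
    scenario_source: str,
    seed: int | None = None,
    n_iterations: int | None = None,
    wtp_grid: Sequence[float] | None = None,
    tariff_gamma: str | None = None,
    extra: dict[str, Any] | None = None,
) -> Path:
    """Write ``manifest.json`` describing a run; returns the manifest path."""
    outdir = Path(outdir)
    manifest = {
        "subcommand": subcommand,
        "scenario_source": scenario_source,
        "seed": seed,
        "n_iterations": n_iterations,
        "wtp_grid": None if wtp_grid is None else {
            "min": float(min(wtp_grid)), "max": float(max(wtp_grid)), "n_points": len(list(wtp_grid)),
        },
        "tariff_gamma": tariff_gamma,
        "package_version": _package_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read an exported CSV with exact float round-trip parsing."""
    return pd.read_csv(path, float_precision="round_trip")
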