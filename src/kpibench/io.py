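"""CSV / YAML interchange for panels, matrices, weights and KPI families.

Panels travel as plain CSV (first column the period label, one column per
variable); variable orientations and the nominant target live in a small
YAML config, not in the CSV.  All writers use a fixed float format so that
identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .dematel import ImpactMatrix, InfluenceIndicators
from .preprocessing import IndicatorPanel, Orientation

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_orientation_config",
    "write_orientation_config",
    "orientation_config_for",
    "read_impact_matrix_csv",
    "write_impact_matrix_csv",
    "write_indicators_csv",
    "write_weights_csv",
    "write_kpi_csv",
    "read_kpi_csv",
]

_FLOAT_FORMAT = "%.10g"


def write_panel_csv(panel: IndicatorPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, float_format=_FLOAT_FORMAT)


def read_panel_csv(
    path: str | Path,
    orientations: dict[str, str] | None = None,
    targets: dict[str, float] | None = None,
    converted: bool = False,
) -> IndicatorPanel:
    frame = pd.read_csv(path, index_col=0)
    return IndicatorPanel.from_frame(frame, orientations=orientations, targets=targets, converted=converted)


def orientation_config_for(panel: IndicatorPanel) -> dict:
    """Orientation/target mapping of a panel, as a YAML-serialisable dict."""
    config: dict = {"orientations": {}, "targets": {}}
    for s in panel.series:
        config["orientations"][s.name] = s.orientation.value
        if s.target is not None:
            config["targets"][s.name] = float(s.target)
    return config


def write_orientation_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_orientation_config(path: str | Path) -> tuple[dict[str, str], dict[str, float]]:
    raw = yaml.safe_load(Path(path).read_text())
    return dict(raw.get("orientations", {})), dict(raw.get("targets", {}))


def read_impact_matrix_csv(path: str | Path, scale_max: int | None = 3) -> ImpactMatrix:
    frame = pd.read_csv(path, index_col=0)
    return ImpactMatrix.from_frame(frame, scale_max=scale_max)


def write_impact_matrix_csv(matrix: ImpactMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def write_indicators_csv(indicators: InfluenceIndicators, path: str | Path) -> None:
    indicators.to_frame().to_csv(path, float_format="%.6f")


def write_weights_csv(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, float_format=_FLOAT_FORMAT)


def write_kpi_csv(family: pd.DataFrame, path: str | Path) -> None:
    family.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_kpi_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
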