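"""Bundled fixtures: the published per-phase performance summaries of the
monitored study, and the default study configuration file.

The monitored study — five serum proteins (IgA, alpha-1 antitrypsin,
prealbumin, lipoprotein(a), ceruloplasmin) on a nephelometer, two control
levels, four phases with changing Westgard rule sets — published only its
per-phase CV/bias/sigma summaries, not the raw control measurements.
Those printed summaries ship here as a first-class dataset so the
cross-analyte roll-ups (phase means, improvement counts) can be recomputed
through the same report-building code the synthetic pipeline uses.

The bundled ``study_config.yaml`` (control targets, peer means, TEa goals)
is synthetic: the study printed no control-material targets, so plausible
values consistent with the published baseline CVs were chosen once.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import List

from .io import StudyConfig, read_study_config
from .model import MetricsSummary

__all__ = [
    "reference_summaries",
    "load_study_config",
    "study_config_path",
    "REFERENCE_TABLE",
]

# Published summary table: per analyte, per phase A-D, the reported
# (CV%, bias%, sigma) triple at the analyte's reporting level.
REFERENCE_TABLE = {
    "IgA": {
        "level": "L3",
        "A": (2.9, 0.07, 5.03),
        "B": (3.1, -0.13, 4.75),
        "C": (2.6, -0.96, 5.20),
        "D": (2.6, -1.09, 5.33),
    },
    "AAT": {
        "level": "L3",
        "A": (5.1, 0.63, 3.09),
        "B": (3.5, -3.25, 4.20),
        "C": (3.9, -2.30, 3.21),
        "D": (3.9, -2.21, 3.25),
    },
    "Prealbumin": {
        "level": "L1",
        "A": (4.3, 1.71, 3.62),
        "B": (5.3, 0.94, 2.88),
        "C": (4.0, 0.26, 2.90),
        "D": (4.0, -0.14, 2.95),
    },
    "Lp(a)": {
        "level": "L1",
        "A": (5.0, 2.29, 3.86),
        "B": (7.2, 0.20, 4.71),
        "C": (8.1, -0.56, 3.76),
        "D": (8.1, -0.34, 3.81),
    },
    "Cp": {
        "level": "L3",
        "A": (3.6, 1.72, 3.15),
        "B": (2.6, -2.19, 1.96),
        "C": (2.6, -3.64, 3.38),
        "D": (2.5, -3.65, 3.49),
    },
}


def reference_summaries() -> List[MetricsSummary]:
    """The published summary matrix as :class:`MetricsSummary` records.

    ``n`` is ``None`` throughout: the underlying per-phase result counts
    were not published.
    """
    out: List[MetricsSummary] = []
    for analyte, cells in REFERENCE_TABLE.items():
        level = cells["level"]
        for phase in ("A", "B", "C", "D"):
            cv, bias, sigma = cells[phase]
            out.append(MetricsSummary(analyte, level, phase, cv, bias, sigma))
    return out


def study_config_path() -> Path:
    """Path of the bundled default study configuration YAML."""
    return Path(resources.files("westgardqc").joinpath("data/study_config.yaml"))


def load_study_config() -> StudyConfig:
    """Read the bundled default study configuration."""
    return read_study_config(study_config_path())
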