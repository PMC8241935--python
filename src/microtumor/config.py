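"""Panel, cohort and run configuration objects.

The antibody panel describes which columns of a count table are biological
targets, which are IgG isotype (background) controls and which are ERCC
spike-in controls; cohort metadata maps tissues to patients, treatment arms
and response labels; :class:`RunConfig` collects every analysis threshold in
one place so a run is fully described by a single config file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

VALID_RESPONSES = {"R", "NR", "mR", "mNR", "unknown"}
VALID_ARMS = {"pembro", "nivo", "ipi-nivo"}
VALID_INDICATIONS = {"GBM", "melanoma"}


@dataclass
class PanelConfig:
    """Antibody panel: targets, isotype controls and ERCC spike-ins.

    Parameters
    ----------
    targets
        Names of the biological protein targets.
    isotype_controls
        Names of the IgG isotype control antibodies (optionally tagged with
        species/isotype, e.g. ``"Ms IgG1"``).
    isotype_map
        Target name -> matched isotype control name, or a list of control
        names whose arithmetic mean is used as the background estimate.
    ercc_controls
        Names of the ERCC spike-in level columns; must be non-empty.
    shared_targets
        Optional availability flags per target: ``"both"``,
        ``"melanoma-only"`` or ``"GBM-only"``.
    """

    targets: list[str]
    isotype_controls: list[str]
    isotype_map: dict[str, str | list[str]]
    ercc_controls: list[str]
    shared_targets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ercc_controls:
            raise ValueError("ercc_controls must be non-empty")
        all_names = list(self.targets) + list(self.isotype_controls) + list(self.ercc_controls)
        if len(set(all_names)) != len(all_names):
            dupes = sorted({n for n in all_names if all_names.count(n) > 1})
            raise ValueError(f"panel names must be unique; duplicated: {dupes}")
        controls = set(self.isotype_controls)
        for t in self.targets:
            if t not in self.isotype_map:
                raise ValueError(f"target {t!r} has no isotype control mapping")
            mapped = self.isotype_map[t]
            names = [mapped] if isinstance(mapped, str) else list(mapped)
            if not names:
                raise ValueError(f"target {t!r} maps to an empty isotype control list")
            unknown = [n for n in names if n not in controls]
            if unknown:
                raise ValueError(
                    f"target {t!r} maps to unknown isotype control(s) {unknown}"
                )

    @property
    def control_columns(self) -> list[str]:
        return list(self.isotype_controls) + list(self.ercc_controls)

    @property
    def all_columns(self) -> list[str]:
        return list(self.targets) + self.control_columns

    def isotype_for(self, target: str) -> list[str]:
        mapped = self.isotype_map[target]
        return [mapped] if isinstance(mapped, str) else list(mapped)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        return cls(
            targets=list(d["targets"]),
            isotype_controls=list(d["isotype_controls"]),
            isotype_map=dict(d["isotype_map"]),
            ercc_controls=list(d["ercc_controls"]),
            shared_targets=dict(d.get("shared_targets", {})),
        )


@dataclass
class TissueInfo:
    patient_id: str
    indication: str
    arm: str
    timepoint: str
    response: str

    def __post_init__(self) -> None:
        if self.response not in VALID_RESPONSES:
            raise ValueError(
                f"response {self.response!r} not in {sorted(VALID_RESPONSES)}"
            )
        if self.indication not in VALID_INDICATIONS:
            raise ValueError(f"unknown indication {self.indication!r}")
        if self.arm not in VALID_ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.timepoint not in {"baseline", "on-treatment"}:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


@dataclass
class CohortMeta:
    """Tissue-level cohort metadata (patient, arm, timepoint, response)."""

    tissues: dict[str, TissueInfo]

    def __post_init__(self) -> None:
        # dict keys are unique by construction; validate entries
        for tid, info in self.tissues.items():
            if not isinstance(info, TissueInfo):
                self.tissues[tid] = TissueInfo(**info)

    def response_labels(self, tissue_ids: Sequence[str]) -> list[str]:
        return [self.tissues[t].response for t in tissue_ids]

    def to_dict(self) -> dict:
        return {t: asdict(info) for t, info in self.tissues.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortMeta":
        return cls(tissues={t: TissueInfo(**v) for t, v in d.items()})


@dataclass
class RunConfig:
    """All analysis thresholds and knobs for one pipeline run.

    Defaults reproduce the published analysis conventions: a 25% CD45+
    immune-rich cutoff, VIP importance at 1.0, elimination thresholds
    VIP < 0.8 and |coefficient| < 0.1, an AUC floor of 0.90, a 0.10
    significance level for the component-selection permutation test, a
    2-fold (log2 effect |1|) volcano cutoff and p-value flags at 0.05/0.10.
    """

    cd45_cutoff: float = 0.25
    vip_keep: float = 1.0
    vip_drop: float = 0.8
    coef_drop: float = 0.1
    auc_floor: float = 0.90
    cv_alpha: float = 0.10
    n_perm: int = 2000
    seed: int = 0
    neighbor_radius: float = 30.0
    effect_cutoff: float = 1.0
    p_cutoffs: tuple[float, float] = (0.05, 0.10)
    a_max: int = 10
    vip_stable: float = 1.15
    min_rois: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.cd45_cutoff < 1:
            raise ValueError("cd45_cutoff must be in (0, 1)")
        positive = {
            "vip_keep": self.vip_keep,
            "vip_drop": self.vip_drop,
            "coef_drop": self.coef_drop,
            "auc_floor": self.auc_floor,
            "cv_alpha": self.cv_alpha,
            "n_perm": self.n_perm,
            "neighbor_radius": self.neighbor_radius,
            "effect_cutoff": self.effect_cutoff,
            "a_max": self.a_max,
            "vip_stable": self.vip_stable,
            "min_rois": self.min_rois,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["p_cutoffs"] = list(self.p_cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "p_cutoffs" in d:
            d["p_cutoffs"] = tuple(d["p_cutoffs"])
        return cls(**d)


def load_config(path: str | Path, overrides: Mapping | None = None) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file; CLI overrides win."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)


def load_panel(path: str | Path) -> PanelConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PanelConfig.from_dict(data)


def save_panel(panel: PanelConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(panel.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(panel.to_dict()))
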