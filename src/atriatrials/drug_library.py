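"""Pore-block anti-arrhythmic drug models and trial-level efficacy accounting.

Each treatment is a :class:`DrugModel`: a fixed fractional block per ionic
current (no rate- or state-dependence).  The registry ships twelve
treatments — vernakalant 10/30 uM, amiodarone 1.5 uM acute, 3.0 uM acute and
three chronic sub-variants with progressive I_K1/I_NaK block, flecainide 1 uM
and 2 uM at two I_Na block levels (the higher reflecting block observed at
fibrillatory rates), and digoxin 5/10 nM — applied to an ionic profile by
multiplying each affected conductance factor by (1 - block).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .cell_population import ConductanceScaling, measure_erp
from .errors import DrugLookupError, ValidationError

#: ionic currents a pore-block model may target, mapped to profile factors
CURRENT_TO_FACTOR = {
    "I_Kur": "g_Kur", "I_Kr": "g_Kr", "I_to": "g_to", "I_K1": "g_K1",
    "I_Ks": "g_Ks", "I_CaL": "g_CaL", "I_NaK": "g_NaK", "I_NCX": "g_NCX",
    "I_Na": "g_Na",
}

REGISTRY_SHA256 = "c9d47ed677d53a01184ead0a57a7ff6e1b6bd4f3a8c7d1be50f7da8f8f8d5882"


@dataclass(frozen=True)
class DrugModel:
    """A named dose/variant with its fractional ionic-current block map."""

    name: str
    dose: str
    variant: str
    block: dict

    def __post_init__(self):
        for cur, frac in self.block.items():
            if cur not in CURRENT_TO_FACTOR:
                raise ValidationError(f"unknown current {cur!r} in drug {self.name}")
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"block fraction outside [0,1]: {cur}={frac}")

    def block_of(self, current: str) -> float:
        """Block fraction of ``current`` (0 for unlisted currents)."""
        if current not in CURRENT_TO_FACTOR:
            raise ValidationError(f"unknown current {current!r}")
        return float(self.block.get(current, 0.0))

    @property
    def label(self) -> str:
        return f"{self.name}:{self.dose}:{self.variant}"


@dataclass
class TrialOutcome:
    """Cohort-level result of one treatment."""

    drug: DrugModel
    n_control_sustained: int
    n_terminated: int
    efficacy: float                      # % of control-sustained episodes terminated
    success: Sequence[bool] = field(default_factory=list)
    erp_shift_ms: float = math.nan       # median refractoriness change vs control


def _load_registry() -> list[DrugModel]:
    raw = resources.files("atriatrials.data").joinpath(
        "drug_registry.json").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REGISTRY_SHA256:
        raise ValidationError(
            f"drug registry checksum mismatch ({digest}); file corrupted?")
    entries = json.loads(raw)["treatments"]
    return [DrugModel(e["name"], e["dose"], e["variant"], e["block"])
            for e in entries]


_REGISTRY: Optional[list[DrugModel]] = None


def registry() -> list[DrugModel]:
    """All twelve registered treatments (checksum-validated, cached)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return list(_REGISTRY)


def get_drug(name: str, dose: str, variant: Optional[str] = None) -> DrugModel:
    """Look up a treatment; ``variant`` may be omitted when unambiguous."""
    name = name.lower()
    matches = [d for d in registry() if d.name == name and d.dose == dose]
    if variant is not None:
        matches = [d for d in matches if d.variant == variant]
    if len(matches) == 1:
        return matches[0]
    valid = ", ".join(d.label for d in registry())
    if not matches:
        raise DrugLookupError(
            f"no treatment {name}:{dose}:{variant}; valid entries: {valid}")
    raise DrugLookupError(
        f"ambiguous treatment {name}:{dose}; specify variant "
        f"({', '.join(d.variant for d in matches)})")


def get_drug_by_label(label: str) -> DrugModel:
    """Parse a 'name:dose[:variant]' label."""
    parts = label.split(":")
    if len(parts) == 2:
        return get_drug(parts[0], parts[1])
    if len(parts) == 3:
        return get_drug(parts[0], parts[1], parts[2])
    raise DrugLookupError(f"malformed drug label {label!r}")


def apply_drug(scaling: ConductanceScaling, drug: DrugModel) -> ConductanceScaling:
    """Profile under drug: each targeted factor multiplied by (1 - block).

    Purely multiplicative, so drug block and LVA ionic remodelling compose in
    either order.
    """
    updates = {CURRENT_TO_FACTOR[cur]: getattr(scaling, CURRENT_TO_FACTOR[cur])
               * (1.0 - frac) for cur, frac in drug.block.items()}
    out = scaling.scaled(**updates)
    out.profile_id = f"{scaling.profile_id}+{drug.label}"
    return out


def _sustained_flags(results) -> np.ndarray:
    return np.array([r.sustained if hasattr(r, "sustained") else bool(r)
                     for r in results], dtype=bool)


def compute_efficacy(control_results, drug_results, drug: Optional[DrugModel] = None
                     ) -> TrialOutcome:
    """Efficacy = % of control-sustained episodes rendered non-sustained.

    ``control_results`` / ``drug_results`` are paired sequences of episode
    results (or booleans).  Episodes not sustained under control are excluded
    (success is only defined where there was AF to terminate).
    """
    ctrl = _sustained_flags(control_results)
    under_drug = _sustained_flags(drug_results)
    if ctrl.shape != under_drug.shape:
        raise ValidationError("control and drug result lists differ in length")
    n_ctrl = int(ctrl.sum())
    if n_ctrl == 0:
        raise ValidationError(
            "efficacy undefined: no control-sustained episodes")
    success = ~under_drug[ctrl]
    eff = 100.0 * success.sum() / n_ctrl
    return TrialOutcome(drug=drug, n_control_sustained=n_ctrl,
                        n_terminated=int(success.sum()), efficacy=float(eff),
                        success=success.tolist())


def refractoriness_shift(scaling: ConductanceScaling, drug: DrugModel,
                         protocol: Optional[dict] = None,
                         dt: float = 0.02) -> float:
    """ERP(drug) - ERP(control), ms, under the S1-S2 capture protocol.

    Measured by capture, so post-repolarization refractoriness under Na+
    block is included.  ``protocol`` may override the S1 train
    (``{"s1_cl": ms, "n_s1": beats}``).  Returns ``+inf`` ("complete
    block") when the profile loses excitability or no premature beat
    captures under drug.
    """
    kw = dict(protocol or {})
    erp_ctrl = measure_erp(scaling, dt=dt, **kw)
    if not math.isfinite(erp_ctrl):
        raise ValidationError(
            f"profile {scaling.profile_id} is not excitable without drug")
    erp_drug = measure_erp(apply_drug(scaling, drug), dt=dt, **kw)
    if math.isnan(erp_drug) or math.isinf(erp_drug):
        return math.inf
    return float(erp_drug - erp_ctrl)
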