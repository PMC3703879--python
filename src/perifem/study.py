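"""Comparative studies: implant-design sweep, in-bone positioning depth,
and marginal bone loss.

Every scenario is meshed, solved and post-processed with identical settings
so that percent changes between scenarios isolate the design variable.
Scenarios that are mechanically identical (labels differing only by the
helical milling, which the axisymmetric mesh does not carry) share one
solve through a signature cache.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as G
from .fem import LoadCase, default_materials, reaction_forces, solve_scenario
from .meshing import make_size_field, mesh_scenario
from .recovery import energy_error_norm, recover_stress
from .stress_risk import (OMEGA_NAMES, RegionReport, build_control_regions,
                          default_strength_limits, region_stats)


class StudyError(RuntimeError):
    pass


@dataclass
class ScenarioResult:
    name: str
    spec: G.ScenarioSpec
    report: RegionReport
    max_risk: float
    energy_error_pct: float
    n_elements: int
    n_nodes: int
    hi_ratio: float
    spec_hash: str
    error: str | None = None


@dataclass
class StudyResult:
    results: dict[str, ScenarioResult]
    failures: dict[str, str] = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        frames = []
        for name, r in sorted(self.results.items()):
            t = r.report.table.copy()
            t.insert(0, "scenario", name)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def value(self, scenario: str, region: str, measure: str,
              statistic: str) -> float:
        return self.results[scenario].report.value(region, measure, statistic)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(outdir / "region_report.csv", index=False,
                            float_format="%.10g", lineterminator="\n")
        prov = {"settings": self.settings,
                "scenarios": {n: {"hash": r.spec_hash,
                                  "max_risk": r.max_risk,
                                  "energy_error_pct": r.energy_error_pct,
                                  "n_elements": r.n_elements,
                                  "n_nodes": r.n_nodes}
                              for n, r in sorted(self.results.items())},
                "failures": self.failures}
        (outdir / "study.json").write_text(
            json.dumps(prov, indent=1, sort_keys=True))


def percent_change(value_ref: float, value_other: float) -> float:
    """Reduction of ``value_other`` relative to ``value_ref`` in percent.

    Positive when the second value is smaller than the reference, matching
    the reading "b is reduced by X % with respect to a".
    """
    if value_ref == 0:
        raise StudyError("reference value is zero")
    return 100.0 * (value_ref - value_other) / value_ref


@dataclass
class StudyRunner:
    """Executes scenarios with shared settings and a signature cache."""

    hi_ratio: float = 0.1
    h0_ratio: float = 0.1
    symmetric: bool = True
    delta_ratio: float = 0.25
    load: LoadCase = field(default_factory=LoadCase)
    recovery_mode: str = "average"
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def run_one(self, spec: G.ScenarioSpec, name: str | None = None
                ) -> ScenarioResult:
        sig = spec.mechanical_signature()
        key = hashlib.sha256(sig.encode()).hexdigest()[:16]
        name = name or spec.implant.label
        if key in self._cache:
            c = self._cache[key]
            return ScenarioResult(name, spec, c.report, c.max_risk,
                                  c.energy_error_pct, c.n_elements,
                                  c.n_nodes, c.hi_ratio, key)
        sc = spec.build()
        size = make_size_field(spec.implant.D_mm,
                               h0_ratio=max(self.h0_ratio, self.hi_ratio),
                               hi_ratio=self.hi_ratio)
        mesh = mesh_scenario(sc, size, seed=self.seed,
                             symmetric=self.symmetric)
        system, u, sig_f = solve_scenario(mesh, default_materials(), self.load)
        regions = build_control_regions(mesh, sc, sig_f,
                                        delta_ratio=self.delta_ratio)
        report = region_stats(sig_f, regions, default_strength_limits())
        rec = recover_stress(mesh, sig_f, mode=self.recovery_mode)
        een = energy_error_norm(mesh, default_materials(), sig_f, rec)
        res = ScenarioResult(name, spec, report, report.max_risk(), float(een),
                             len(mesh.elements), len(mesh.nodes),
                             self.hi_ratio, key)
        self._cache[key] = res
        return res

    def run_study(self, scenarios: dict[str, G.ScenarioSpec]) -> StudyResult:
        results, failures = {}, {}
        for name, spec in scenarios.items():
            try:
                results[name] = self.run_one(spec, name)
            except Exception as exc:       # record and continue
                failures[name] = f"{type(exc).__name__}: {exc}"
        return StudyResult(results, failures, settings={
            "hi_ratio": self.hi_ratio, "symmetric": self.symmetric,
            "delta_ratio": self.delta_ratio, "seed": self.seed,
            "load_N": list(self.load.force_vector)})


# --------------------------------------------------------------------------- #
# the three studies
# --------------------------------------------------------------------------- #

def p1_sweep_scenarios(labels=None) -> dict[str, G.ScenarioSpec]:
    """All catalogue implants subcrestally placed at P1 with apposition."""
    cat = G.implant_catalogue()
    labels = labels or list(cat)
    placement = G.PlacementSpec.from_code("P1")
    morph = G.CrestalMorphology(G.MorphologyKind.APPOSITION)
    return {lab: G.ScenarioSpec(cat[lab], placement, morph)
            for lab in labels}


def positioning_scenarios(label: str = "8",
                          p0_bone_loss: float = 0.10
                          ) -> dict[str, G.ScenarioSpec]:
    """P0 (with cratering), P05 and P1 (with apposition) for one implant."""
    cat = G.implant_catalogue()
    out = {}
    for code in ("P0", "P05", "P1"):
        placement = G.PlacementSpec.from_code(code)
        morph = G.CrestalMorphology.for_placement(
            placement, bone_loss_fraction=p0_bone_loss)
        out[f"{label}/{code}"] = G.ScenarioSpec(cat[label], placement, morph)
    return out


def boneloss_scenarios(label: str = "8",
                       fractions=(0.0, 0.10, 0.25, 0.50)
                       ) -> dict[str, G.ScenarioSpec]:
    cat = G.implant_catalogue()
    placement = G.PlacementSpec.from_code("P0")
    out = {}
    for f in fractions:
        kind = G.MorphologyKind.BONE_LOSS if f > 0 else G.MorphologyKind.PRISTINE
        morph = G.CrestalMorphology(kind, bone_loss_fraction=f)
        out[f"{label}/P0/loss{int(round(100 * f))}"] = \
            G.ScenarioSpec(cat[label], placement, morph)
    return out


def boneloss_sweep(runner: StudyRunner, label: str = "8",
                   fractions=(0.0, 0.10, 0.25, 0.50)):
    """Bone-loss study: peaks per region and percent increase vs no loss."""
    study = runner.run_study(boneloss_scenarios(label, fractions))
    rows = []
    base_name = f"{label}/P0/loss0"
    for f in fractions:
        name = f"{label}/P0/loss{int(round(100 * f))}"
        if name not in study.results:
            continue
        for region in OMEGA_NAMES.values():
            for meas in ("sigma_vm", "sigma_t", "sigma_c_abs", "risk"):
                peak = study.value(name, region, meas, "peak")
                base = study.value(base_name, region, meas, "peak")
                rows.append((f, region, meas, peak,
                             -percent_change(base, peak) if base else np.nan))
    table = pd.DataFrame(rows, columns=["bone_loss_fraction", "region",
                                        "measure", "peak",
                                        "increase_vs_noloss_pct"])
    return study, table


def trabecular_peak(study: StudyResult, scenario: str, measure: str) -> float:
    """Peak over the union of the three trabecular subregions."""
    return max(study.value(scenario, r, measure, "peak")
               for r in ("trab_crest", "trab_mid", "trab_apex"))


def comparison_table(study: StudyResult,
                     pairs: list[tuple[str, str, str, str, str]]
                     ) -> pd.DataFrame:
    """Percent changes for named scenario pairs.

    Each pair is (reference, other, region, measure, statistic); the sign
    convention is a positive number when the second scenario is lower.
    """
    rows = []
    for ref, other, region, measure, stat in pairs:
        a = study.value(ref, region, measure, stat)
        b = study.value(other, region, measure, stat)
        rows.append((ref, other, region, measure, stat, a, b,
                     percent_change(a, b)))
    return pd.DataFrame(rows, columns=["reference", "other", "region",
                                       "measure", "statistic", "ref_value",
                                       "other_value", "reduction_pct"])
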