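"""Synthetic hypochromic-microcytic CBC cohorts.

The reference cohort (708 beta-thalassemia trait, 470 iron-deficiency
anemia patients; all CBC variables differing between groups, BTT with the
lower MCV) is not publicly deposited, so this module draws labeled stand-in
cohorts with the same structure: per group, a truncated correlated
multivariate normal over (hb, hct, mcv, mch, mchc, rbc, log rdw) rejected
against the inclusion box (MCV < 80, MCH < 27, 8 <= Hb < 12/13 by sex),
plus confirmatory markers consistent with each group's gold-standard rule
(BTT: HbA2 > 3.5 % and ferritin >= 15 ng/mL; IDA: ferritin < 15 ng/mL and
HbA2 <= 3.5 %).  RDW and ferritin are sampled on the log scale for
positivity and right skew.

Defaults are literature-typical group locations (BTT MCV in the low 60s fL
with high RBC; IDA MCV in the low 70s fL with elevated RDW and low
ferritin), configurable via :class:`GroupModel`.  ``separation`` scales the
between-group mean difference: 0 collapses both groups onto the common
midpoint (no signal), 1 is the default geometry.

Identical (config, model) pairs give identical cohorts, byte for byte once
written to CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import (
    BTT,
    IDA,
    CBC_FIELDS,
    CohortCriteria,
    PatientRecord,
    apply_inclusion_exclusion,
)

__all__ = [
    "GroupModel",
    "SimulationConfig",
    "default_group_model",
    "generate_cohort",
    "check_group_separation",
    "load_simulation_config",
]

#: order of the correlated block; rdw is sampled as log(rdw)
_MVN_FIELDS = ("hb", "hct", "mcv", "mch", "mchc", "rbc", "rdw")

#: rounding (decimal places) applied to emitted values, matching analyser output
_PRECISION = {
    "hb": 1, "hct": 1, "mcv": 1, "mch": 1, "mchc": 1, "rbc": 2, "rdw": 1,
    "hba2": 1, "ferritin": 1, "serum_iron": 1, "tibc": 1,
}

_DEFAULT_CORR = np.array([
    #  hb    hct   mcv   mch   mchc  rbc   lrdw
    [1.00, 0.85, 0.35, 0.55, 0.45, 0.40, -0.25],   # hb
    [0.85, 1.00, 0.45, 0.45, 0.15, 0.50, -0.20],   # hct
    [0.35, 0.45, 1.00, 0.70, 0.20, -0.25, -0.30],  # mcv
    [0.55, 0.45, 0.70, 1.00, 0.55, -0.20, -0.30],  # mch
    [0.45, 0.15, 0.20, 0.55, 1.00, 0.05, -0.15],   # mchc
    [0.40, 0.50, -0.25, -0.20, 0.05, 1.00, 0.10],  # rbc
    [-0.25, -0.20, -0.30, -0.30, -0.15, 0.10, 1.00],  # log rdw
])


def _nearest_psd(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    eigval, eigvec = np.linalg.eigh((corr + corr.T) / 2)
    if eigval.min() >= floor:
        return corr
    clipped = eigvec @ np.diag(np.maximum(eigval, floor)) @ eigvec.T
    d = np.sqrt(np.diag(clipped))
    return clipped / np.outer(d, d)


@dataclass(frozen=True)
class GroupModel:
    """Distributional model of the two diagnostic groups.

    ``means``/``sds`` map group -> values for (hb, hct, mcv, mch, mchc, rbc,
    rdw) in their natural units (rdw is internally log-transformed); HbA2 is
    truncated normal and ferritin log-normal, each consistent with the
    group's labeling rule.
    """

    means: dict = field(default_factory=lambda: {
        BTT: {"hb": 10.5, "hct": 33.5, "mcv": 61.5, "mch": 19.5,
              "mchc": 31.2, "rbc": 5.6, "rdw": 14.5},
        IDA: {"hb": 9.6, "hct": 31.5, "mcv": 72.5, "mch": 21.8,
              "mchc": 29.8, "rbc": 4.35, "rdw": 17.5},
    })
    sds: dict = field(default_factory=lambda: {
        BTT: {"hb": 0.9, "hct": 2.8, "mcv": 4.0, "mch": 1.4,
              "mchc": 1.0, "rbc": 0.65, "rdw": 1.3},
        IDA: {"hb": 1.0, "hct": 3.0, "mcv": 4.5, "mch": 1.6,
              "mchc": 1.1, "rbc": 0.60, "rdw": 2.0},
    })
    corr: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    hba2: dict = field(default_factory=lambda: {
        BTT: {"mean": 4.6, "sd": 0.6, "low": 3.55, "high": 8.0},
        IDA: {"mean": 2.4, "sd": 0.5, "low": 0.5, "high": 3.45},
    })
    ferritin: dict = field(default_factory=lambda: {
        # log-normal: median and sigma on the log scale, truncated to the rule
        BTT: {"median": 60.0, "sigma": 0.6, "low": 15.0, "high": 400.0},
        IDA: {"median": 7.0, "sigma": 0.5, "low": 1.0, "high": 14.9},
    })
    serum_iron: dict = field(default_factory=lambda: {
        BTT: {"mean": 85.0, "sd": 22.0}, IDA: {"mean": 30.0, "sd": 10.0},
    })
    tibc: dict = field(default_factory=lambda: {
        BTT: {"mean": 330.0, "sd": 35.0}, IDA: {"mean": 420.0, "sd": 45.0},
    })
    female_fraction: float = 0.6
    criteria: CohortCriteria = field(default_factory=CohortCriteria)

    def __post_init__(self):
        object.__setattr__(self, "corr", _nearest_psd(np.asarray(self.corr)))
        if self.means[BTT]["mcv"] >= self.means[IDA]["mcv"]:
            warnings.warn("BTT mean MCV is not below IDA mean MCV")


def default_group_model() -> GroupModel:
    return GroupModel()


@dataclass(frozen=True)
class SimulationConfig:
    n_ida: int = 470
    n_btt: int = 708
    seed: int = 0
    separation: float = 1.0

    def __post_init__(self):
        if self.n_ida < 0 or self.n_btt < 0:
            raise ValueError("group sizes must be non-negative")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def load_simulation_config(path) -> tuple[SimulationConfig, GroupModel]:
    """Read a YAML config: counts/seed/separation plus optional model override."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    cfg = SimulationConfig(
        n_ida=int(raw.get("n_ida", 470)),
        n_btt=int(raw.get("n_btt", 708)),
        seed=int(raw.get("seed", 0)),
        separation=float(raw.get("separation", 1.0)),
    )
    model = default_group_model()
    overrides = raw.get("model") or {}
    if overrides:
        kwargs = {}
        for key in ("means", "sds", "hba2", "ferritin", "serum_iron", "tibc"):
            if key in overrides:
                base = {g: dict(v) for g, v in getattr(model, key).items()}
                for group, vals in overrides[key].items():
                    base[group].update(vals)
                kwargs[key] = base
        if "female_fraction" in overrides:
            kwargs["female_fraction"] = float(overrides["female_fraction"])
        model = dc_replace(model, **kwargs)
    return cfg, model


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _group_mean_vectors(model: GroupModel, separation: float) -> dict:
    mid = {
        f: (model.means[BTT][f] + model.means[IDA][f]) / 2 for f in _MVN_FIELDS
    }
    out = {}
    for group in (BTT, IDA):
        out[group] = {
            f: mid[f] + separation * (model.means[group][f] - mid[f])
            for f in _MVN_FIELDS
        }
    return out


def generate_cohort(
    config: SimulationConfig,
    model: GroupModel | None = None,
    min_acceptance: float = 0.01,
) -> list[PatientRecord]:
    """Draw a labeled cohort; every emitted record passes the inclusion filter
    and obeys its group's HbA2/ferritin rule.

    Rejection sampling guarantees the requested group sizes exactly.  A
    truncation acceptance rate below ``min_acceptance`` raises with advice to
    adjust the model rather than looping forever.
    """
    model = model or default_group_model()
    if config.n_ida == 0 or config.n_btt == 0:
        warnings.warn("a group has size 0; downstream two-class analyses will fail")
    rng = np.random.default_rng(config.seed)
    means = _group_mean_vectors(model, config.separation)
    records: list[PatientRecord] = []
    counter = 0
    for group, n_wanted in ((BTT, config.n_btt), (IDA, config.n_ida)):
        if n_wanted == 0:
            continue
        mu = np.array([
            np.log(means[group]["rdw"]) if f == "rdw" else means[group][f]
            for f in _MVN_FIELDS
        ])
        sd = np.array([
            model.sds[group]["rdw"] / model.means[group]["rdw"]  # log-scale sd
            if f == "rdw" else model.sds[group][f]
            for f in _MVN_FIELDS
        ])
        cov = model.corr * np.outer(sd, sd)
        accepted = 0
        attempts = 0
        while accepted < n_wanted:
            batch = max(256, 2 * (n_wanted - accepted))
            draws = rng.multivariate_normal(mu, cov, size=batch, method="cholesky")
            h = model.hba2[group]
            hba2 = _truncnorm(rng, h["mean"], h["sd"], h["low"], h["high"], batch)
            fe = model.ferritin[group]
            ferritin = np.exp(
                _truncnorm(rng, np.log(fe["median"]), fe["sigma"],
                           np.log(fe["low"]), np.log(fe["high"]), batch)
            )
            iron = rng.normal(model.serum_iron[group]["mean"],
                              model.serum_iron[group]["sd"], batch)
            tibc = rng.normal(model.tibc[group]["mean"],
                              model.tibc[group]["sd"], batch)
            female = rng.random(batch) < model.female_fraction
            for i in range(batch):
                attempts += 1
                if accepted >= n_wanted:
                    break
                values = dict(zip(_MVN_FIELDS, draws[i]))
                values["rdw"] = float(np.exp(values["rdw"]))
                values["hba2"] = float(hba2[i])
                values["ferritin"] = float(ferritin[i])
                values["serum_iron"] = float(abs(iron[i]))
                values["tibc"] = float(abs(tibc[i]))
                rounded = {
                    k: round(float(v), _PRECISION[k]) for k, v in values.items()
                }
                if any(v <= 0 for v in rounded.values()):
                    continue
                record = PatientRecord(
                    sex="female" if female[i] else "male",
                    record_id=f"S{counter + 1:05d}",
                    **rounded,
                )
                kept, _ = _safe_filter(record, model.criteria)
                if kept is None or kept.label != group:
                    continue
                records.append(kept)
                counter += 1
                accepted += 1
            if attempts > 1000 and accepted / attempts < min_acceptance:
                raise RuntimeError(
                    f"acceptance rate {accepted/attempts:.3f} for group {group} "
                    "below floor; adjust the group model or criteria"
                )
    # deterministic shuffle so the groups are interleaved as in a real intake
    order = rng.permutation(len(records))
    shuffled = [records[i] for i in order]
    return [
        dc_replace(r, record_id=f"S{i + 1:05d}") for i, r in enumerate(shuffled)
    ]


def _safe_filter(record: PatientRecord, criteria: CohortCriteria):
    kept, rejected = apply_inclusion_exclusion([record], criteria)
    return (kept[0] if kept else None), rejected


def check_group_separation(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Two-sample Mann-Whitney rank test per CBC variable between groups.

    A generator self-test: under the default model every variable should
    separate the groups decisively; under ``separation = 0`` p-values are
    approximately uniform.
    """
    by_group = {BTT: [], IDA: []}
    for record in cohort:
        if record.label in by_group:
            by_group[record.label].append(record)
    if min(len(v) for v in by_group.values()) == 0:
        raise ValueError("both groups must be present")
    if min(len(v) for v in by_group.values()) < 10:
        warnings.warn("fewer than 10 records in a group; test is unreliable")
    rows = []
    for name in CBC_FIELDS:
        a = np.array([getattr(r, name) for r in by_group[BTT]], dtype=float)
        b = np.array([getattr(r, name) for r in by_group[IDA]], dtype=float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            rows.append((name, np.nan, np.nan, "degenerate: constant values"))
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((name, float(res.statistic), float(res.pvalue), ""))
    return pd.DataFrame(rows, columns=["variable", "statistic", "pvalue", "note"])
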