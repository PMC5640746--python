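"""Synthetic referral-network studies with known, planted structure.

The real survey data behind this kind of study (19 regional mental-health
service networks, a tie survey among services, and ~80 cluster-sampled
patients per network) are not publicly deposited, so every downstream
stage is exercised on simulated studies whose generating parameters are
known exactly.  The generator plants:

* network structure — a typed inhomogeneous random digraph
  (stochastic-block-style): each ordered pair is tied independently with a
  baseline probability, multiplied by a within-type factor (the homophily
  dial) and a hub-attraction factor for ties into a designated hub (the
  centralization dial).  Present ties get an ordinal rating ("often" with
  a configurable share, else "sometimes") so both dichotomization rules
  have something to disagree about.
* outcomes — a patient's latent continuity score is a linear model:
  intercept + standardized network-metric effects + patient covariates +
  a network random intercept + Gaussian residual, discretized into 31
  valid 1..5 items whose sum matches the latent total.  Social integration
  comes from an ordered-threshold (proportional-odds) model on an
  analogous logistic latent, decomposed into the four SIX components.

Defaults mirror the descriptive statistics of the national reform
evaluation this pipeline is modeled on: 19 networks of 11-115 services with the reported
service-type mix, 52% service participation, 80 patients per network as
8 recruitment clusters x 10 patients, mean continuity ~115.6 (sd ~14),
mean SIX ~3.1, continuity ICC a few percent and SIX latent ICC ~10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from carenet.network_build import build_network
from carenet.network_metrics import metrics_table
from carenet.survey_io import (
    DIAGNOSES,
    SERVICE_TYPES,
    N_ACSS_ITEMS,
    PatientRecord,
    ServiceNode,
    TieRecord,
    write_patients,
    write_roster,
    write_ties,
)

__all__ = ["SimulationConfig", "SyntheticStudy", "generate_network", "generate_patients", "generate_study"]

#: Study-average service-type mix used as the default composition target.
DEFAULT_TYPE_MIX: dict[str, float] = {
    "primary_care": 0.128,
    "community_mental_health": 0.108,
    "crisis_outreach": 0.100,
    "rehabilitation": 0.116,
    "social_services": 0.209,
    "psychiatric_ward": 0.171,
    "sheltered_housing": 0.102,
    "nursing_home": 0.035,
    "other": 0.031,
}

#: Recruitment design: ten patients per cluster from each of eight services —
#: two primary-care/community services, two crisis/outreach teams, two
#: psychiatric wards, one long-term residential service, one social or
#: rehabilitation service.
DEFAULT_RECRUITMENT_CLUSTERS: tuple[str, ...] = (
    "primary_care",
    "community_mental_health",
    "crisis_outreach",
    "crisis_outreach",
    "psychiatric_ward",
    "psychiatric_ward",
    "sheltered_housing",
    "social_services",
)

DIAGNOSIS_PROBS = (0.286, 0.254, 0.174, 0.151, 0.065, 0.070)


@dataclass
class SimulationConfig:
    """All dials of the synthetic study.

    Tie model probabilities are per ordered pair; ``within_type_factor``
    multiplies the tie probability when both endpoints share a service
    type (<1 plants heterophily, >1 homophily); ``hub_boost`` multiplies
    the probability of ties *into* the designated hub service.  Outcome
    effects are per standard deviation of the network metric:
    ``continuity_effects`` on the standardized-continuity scale,
    ``six_effects`` on the latent log-odds scale.
    """

    n_networks: int = 19
    size_min: int = 11
    size_max: int = 115
    type_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    # tie model
    baseline_tie_prob: float = 0.45
    within_type_factor: float = 0.6
    hub_boost: float = 2.0
    often_share: float = 0.5
    organizational_tie_prob: float = 0.10
    participation_rate: float = 0.52
    # patient sampling
    patients_per_network: int = 80
    cluster_size: int = 10
    recruitment_clusters: tuple[str, ...] = DEFAULT_RECRUITMENT_CLUSTERS
    # continuity outcome model
    acss_intercept: float = 115.6
    continuity_effects: dict[str, float] = field(
        default_factory=lambda: {"coleman_crisis_outreach": 0.08}
    )
    acss_age_effect: float = 0.05
    acss_male_effect: float = -1.0
    acss_honos_effect: float = -0.3
    network_intercept_sd: float = 2.5
    residual_sd: float = 14.0
    # social-integration outcome model (latent logistic scale)
    six_effects: dict[str, float] = field(default_factory=lambda: {"n_services": -0.3})
    six_age_effect: float = 0.0
    six_male_effect: float = 0.0
    six_honos_effect: float = -0.05
    six_network_intercept_sd: float = 0.6
    six_target_mean: float = 3.1
    six_threshold_spacing: float = 1.0
    # data hygiene
    missing_item_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_tie_prob",
            "within_type_factor",
            "hub_boost",
            "often_share",
            "organizational_tie_prob",
            "participation_rate",
            "missing_item_rate",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in ("baseline_tie_prob", "often_share", "participation_rate", "missing_item_rate"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.size_min < 3:
            raise ValueError("size_min must be >= 3")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        unknown = set(self.type_mix) - set(SERVICE_TYPES)
        if unknown:
            raise ValueError(f"unknown service types in type_mix: {sorted(unknown)}")
        total = sum(self.type_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"type_mix must sum to 1, got {total}")
        self.recruitment_clusters = tuple(self.recruitment_clusters)
        if self.patients_per_network != self.cluster_size * len(self.recruitment_clusters):
            raise ValueError(
                "patients_per_network must equal cluster_size x number of recruitment clusters "
                f"({self.cluster_size} x {len(self.recruitment_clusters)})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticStudy:
    """One simulated study: survey tables plus the planted truth."""

    config: SimulationConfig
    roster: list[ServiceNode]
    ties: list[TieRecord]
    patients: list[PatientRecord]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "services": out / "services.csv",
            "ties": out / "ties.csv",
            "patients": out / "patients.csv",
        }
        write_roster(self.roster, paths["services"])
        write_ties(self.ties, paths["ties"])
        write_patients(self.patients, paths["patients"])
        return paths


def _network_rng(config: SimulationConfig, network_index: int) -> np.random.Generator:
    # deterministic per-network substream derived from (seed, index)
    return np.random.default_rng([int(config.seed), int(network_index)])


def generate_network(
    config: SimulationConfig,
    network_index: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ServiceNode], list[TieRecord]]:
    """Draw one network's roster and tie-survey records.

    Network size is drawn from a right-skewed Beta(1.2, 2) over the
    configured range (small networks are more common than large ones, as
    in the real size distribution).  Only participating services report
    ties; reports about non-participants are kept, which is what the
    full-matrix sensitivity scope consumes.  Most present ties are emitted
    as ``referral_sent`` or ``info_exchange`` by the source service; when
    the target also participated, a third of them are instead recorded as
    the mirror-image ``referral_received`` report by the target, so the
    reversal convention is exercised by every simulated study.
    """
    if rng is None:
        rng = _network_rng(config, network_index)
    net_id = f"N{network_index + 1:02d}"
    span = config.size_max - config.size_min
    n = int(config.size_min + round(float(rng.beta(1.2, 2.0)) * span))
    types = list(rng.choice(SERVICE_TYPES, size=n, p=[config.type_mix.get(t, 0.0) for t in SERVICE_TYPES]))
    participated = rng.random(n) < config.participation_rate
    # guarantee enough respondents for the metrics to be defined
    while participated.sum() < 3:
        participated[int(rng.integers(n))] = True
    roster = [
        ServiceNode(
            service_id=f"{net_id}S{i + 1:03d}",
            network_id=net_id,
            service_type=types[i],
            participated=bool(participated[i]),
        )
        for i in range(n)
    ]
    hub = next(i for i in range(n) if participated[i])

    type_codes = np.array([SERVICE_TYPES.index(t) for t in types])
    ids = [s.service_id for s in roster]
    ties: list[TieRecord] = []
    for i in range(n):
        if not participated[i]:
            continue
        p = np.full(n, config.baseline_tie_prob)
        p[type_codes == type_codes[i]] *= config.within_type_factor
        p[hub] *= config.hub_boost
        p[i] = 0.0
        np.clip(p, 0.0, 1.0, out=p)
        present = rng.random(n) < p
        freq = np.where(rng.random(n) < config.often_share, 2, 1)
        kind_draw = rng.random(n)
        org = rng.random(n) < config.organizational_tie_prob
        org_freq = np.where(rng.random(n) < config.often_share, 2, 1)
        org[i] = False
        for j in np.flatnonzero(present):
            if kind_draw[j] < 1 / 3 and participated[j]:
                # mirror report: target says it received a referral from i
                ties.append(
                    TieRecord(
                        network_id=net_id,
                        reporter_id=ids[j],
                        alter_id=ids[i],
                        relation_kind="referral_received",
                        frequency=int(freq[j]),
                    )
                )
            else:
                kind = "referral_sent" if kind_draw[j] < 2 / 3 else "info_exchange"
                ties.append(
                    TieRecord(
                        network_id=net_id,
                        reporter_id=ids[i],
                        alter_id=ids[j],
                        relation_kind=kind,
                        frequency=int(freq[j]),
                    )
                )
        for j in np.flatnonzero(org):
            ties.append(
                TieRecord(
                    network_id=net_id,
                    reporter_id=ids[i],
                    alter_id=ids[j],
                    relation_kind="organizational",
                    frequency=int(org_freq[j]),
                )
            )
    return roster, ties


def _six_thresholds(config: SimulationConfig) -> np.ndarray:
    """Six ordered cutpoints whose null-model mean total hits the target.

    With a standard-logistic latent, E[total] = sum_j sigmoid(-tau_j); the
    common shift c of equally spaced cutpoints is solved by root finding.
    """
    offsets = config.six_threshold_spacing * (np.arange(6) - 2.5)

    def mean_total(c: float) -> float:
        return float(np.sum(expit(-(c + offsets)))) - config.six_target_mean

    c = brentq(mean_total, -20.0, 20.0)
    return c + offsets


def _standardize_metrics(metric_rows: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    """Z-score metrics across networks; undefined values (e.g. a Coleman
    index for a type with no out-ties) are set to the mean, i.e. zero
    effect for that network."""
    z = pd.DataFrame(index=metric_rows.index)
    for name in names:
        col = metric_rows[name].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"metric {name!r} is constant (or all-missing) across networks")
        z[name] = ((col - col.mean()) / sd).fillna(0.0)
    return z


def _acss_items_from_total(total: float, rng: np.random.Generator) -> list[int]:
    """Distribute a latent total over 31 items, each 1..5, preserving the sum."""
    t = int(round(min(max(total, 31.0), 155.0)))
    base, rem = divmod(t - N_ACSS_ITEMS, N_ACSS_ITEMS)
    items = np.full(N_ACSS_ITEMS, 1 + base, dtype=int)
    if rem:
        bump = rng.choice(N_ACSS_ITEMS, size=rem, replace=False)
        items[bump] += 1
    # spread item-level variation without moving the sum
    for _ in range(N_ACSS_ITEMS):
        a, b = rng.integers(0, N_ACSS_ITEMS, size=2)
        if items[a] < 5 and items[b] > 1 and a != b:
            items[a] += 1
            items[b] -= 1
    return items.tolist()


def _six_components(total: int) -> tuple[int, int, int, int]:
    emp = min(2, total)
    rest = total - emp
    acc = min(2, rest)
    rest -= acc
    fam = min(1, rest)
    rest -= fam
    fri = min(1, rest)
    return emp, acc, fam, fri


def generate_patients(
    config: SimulationConfig,
    metric_rows: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> list[PatientRecord]:
    """Draw cluster-sampled patients with planted network effects.

    ``metric_rows`` is the per-network metric table (one row per network,
    as returned by :func:`carenet.network_metrics.metrics_table`); effects
    are applied to metrics standardized across the study's networks, so a
    coefficient of 0.15 means 0.15 outcome standard deviations per metric
    standard deviation.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 10_000_019])
    needed = sorted(set(config.continuity_effects) | set(config.six_effects))
    z = _standardize_metrics(metric_rows, needed) if needed else pd.DataFrame(index=metric_rows.index)
    sigma_y = math.hypot(config.network_intercept_sd, config.residual_sd)
    thresholds = _six_thresholds(config)

    patients: list[PatientRecord] = []
    for net_id in metric_rows.index:
        u_acss = rng.normal(0.0, config.network_intercept_sd)
        u_six = rng.normal(0.0, config.six_network_intercept_sd)
        acss_net = sum(
            beta * sigma_y * z.loc[net_id, m] for m, beta in config.continuity_effects.items()
        )
        six_net = sum(beta * z.loc[net_id, m] for m, beta in config.six_effects.items())
        k = 0
        for cluster_type in config.recruitment_clusters:
            for _ in range(config.cluster_size):
                k += 1
                age = float(np.clip(rng.normal(45.7, 12.6), 18.0, 90.0))
                male = rng.random() < 0.48
                honos = int(np.clip(round(rng.normal(12.5, 6.5)), 0, 48))
                diagnosis = DIAGNOSES[rng.choice(len(DIAGNOSES), p=DIAGNOSIS_PROBS)]
                latent = (
                    config.acss_intercept
                    + acss_net
                    + u_acss
                    + config.acss_age_effect * (age - 45.7)
                    + config.acss_male_effect * (1.0 if male else 0.0)
                    + config.acss_honos_effect * (honos - 12.5)
                    + rng.normal(0.0, config.residual_sd)
                )
                items: list[Optional[int]] = list(_acss_items_from_total(latent, rng))
                if config.missing_item_rate > 0 and rng.random() < config.missing_item_rate:
                    items[int(rng.integers(N_ACSS_ITEMS))] = None
                six_latent = (
                    six_net
                    + u_six
                    + config.six_age_effect * (age - 45.7)
                    + config.six_male_effect * (1.0 if male else 0.0)
                    + config.six_honos_effect * (honos - 12.5)
                    + rng.logistic(0.0, 1.0)
                )
                six = int(np.sum(six_latent > thresholds))
                emp, acc, fam, fri = _six_components(six)
                patients.append(
                    PatientRecord(
                        patient_id=f"{net_id}P{k:03d}",
                        network_id=str(net_id),
                        recruitment_service_type=cluster_type,
                        acss_items=items,
                        six_employment=emp,
                        six_accommodation=acc,
                        six_family=fam,
                        six_friends=fri,
                        age=round(age, 1),
                        sex="male" if male else "female",
                        honos=honos,
                        diagnosis=diagnosis,
                        n_outpatient=int(rng.poisson(1.5)),
                        n_social=int(rng.poisson(0.7)),
                        n_residential=int(rng.poisson(0.7)),
                    )
                )
    return patients


def generate_study(config: SimulationConfig, out_dir: Optional[str | Path] = None) -> SyntheticStudy:
    """Generate a full study (roster, ties, patients), optionally writing CSVs.

    Deterministic given ``config`` (including its seed): each network uses
    a substream derived from ``(seed, network_index)`` and the patient
    stage its own substream, so changing one dial never reshuffles
    unrelated draws.  Patient outcomes are driven by the metrics of the
    main-rule networks (participants only, "sometimes or often").
    """
    roster: list[ServiceNode] = []
    ties: list[TieRecord] = []
    networks = []
    for idx in range(config.n_networks):
        r, t = generate_network(config, idx)
        roster.extend(r)
        ties.extend(t)
        networks.append(build_network(r, t))
    metric_rows, _ = metrics_table(networks)
    patients = generate_patients(config, metric_rows)
    study = SyntheticStudy(config=config, roster=roster, ties=ties, patients=patients)
    if out_dir is not None:
        study.write(out_dir)
    return study
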