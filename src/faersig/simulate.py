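"""Synthetic spontaneous-report generator with planted association strengths.

The generator emits DEMO/DRUG/REAC quarterly files in the same "$"-dialect
the ingest module reads, plus a truth table of the planted drug–event odds
ratios, so every pipeline stage can be exercised and calibrated without a
multi-gigabyte database download.

Sampling model, per case:

* drug exposures are independent Bernoulli draws from per-drug marginal
  probabilities;
* each event occurs with probability derived from its background odds
  ``p/(1-p)`` multiplied by the planted odds ratio ``rho`` of every exposed
  planted drug (multiplicative on the odds scale, so a single-exposure
  case has reporting odds exactly ``rho`` times the background and the
  planted value is the estimand of the downstream ROR);
* report dates are uniform over the 2018-01-01..2022-12-31 window and the
  quarter of the date decides which file set the record lands in;
* with probability ``duplicate_rate`` the case is re-emitted as a higher
  CASEVERSION with a later FDA date, exercising deduplication.

Identifiers are transparent: CASEID is a sequential integer and
PRIMARYID = CASEID*100 + CASEVERSION.  A fixed config and seed reproduce a
byte-identical file set.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .normalize import normalize_key

WINDOW_START = np.datetime64("2018-01-01")
WINDOW_END = np.datetime64("2022-12-31")  # inclusive
_N_DAYS = int((WINDOW_END - WINDOW_START) / np.timedelta64(1, "D")) + 1

DEFAULT_ROLE_MIX: Mapping[str, float] = {"PS": 0.6, "SS": 0.3, "C": 0.1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition description for one synthetic dataset."""

    n_cases: int
    #: (canonical drug name, marginal exposure probability)
    drugs: tuple[tuple[str, float], ...]
    #: (preferred event term, background occurrence probability)
    events: tuple[tuple[str, float], ...]
    #: planted (drug, event) -> target odds ratio rho; unlisted pairs are null
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    duplicate_rate: float = 0.1
    role_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ROLE_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError(f"n_cases must be >= 1, got {self.n_cases}")
        if not self.drugs or not self.events:
            raise ConfigError("need at least one drug and one event")
        for name, p in list(self.drugs) + list(self.events):
            if not (0.0 < p < 1.0):
                raise ConfigError(f"probability for {name!r} must be in (0,1), got {p}")
        drug_names = {normalize_key(n) for n, _ in self.drugs}
        event_names = {normalize_key(n) for n, _ in self.events}
        if len(drug_names) != len(self.drugs) or len(event_names) != len(self.events):
            raise ConfigError("drug and event names must be unique after key-normalization")
        for (drug, event), rho in self.effects.items():
            if rho <= 0 or not math.isfinite(rho):
                raise ConfigError(f"effect for ({drug}, {event}) must be a finite rho > 0, got {rho}")
            if normalize_key(drug) not in drug_names:
                raise ConfigError(f"planted effect names unknown drug {drug!r}")
            if normalize_key(event) not in event_names:
                raise ConfigError(f"planted effect names unknown event {event!r}")
        if not (0.0 <= self.duplicate_rate <= 1.0):
            raise ConfigError(f"duplicate_rate must be in [0,1], got {self.duplicate_rate}")
        total = sum(self.role_mix.values())
        if not self.role_mix or abs(total - 1.0) > 1e-9:
            raise ConfigError(f"role_mix must sum to 1, got {total}")
        for role in self.role_mix:
            if role not in ("PS", "SS", "C", "I"):
                raise ConfigError(f"unknown role code {role!r} in role_mix")
        # worst-case combined odds must stay finite (spec: the offending
        # pair is named when an event's probability degenerates)
        for event, p in self.events:
            odds = p / (1.0 - p)
            for (drug, ev), rho in self.effects.items():
                if normalize_key(ev) == normalize_key(event) and rho > 1:
                    odds *= rho
                    if not math.isfinite(odds) or odds / (1.0 + odds) >= 1.0:
                        raise ConfigError(
                            f"combined event probability for ({drug}, {event}) reaches 1"
                        )

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticConfig":
        """A small realistic demo: a 12-drug panel, four symptoms, mixed effects."""
        drugs = tuple((f"DRUG_{chr(65 + i)}", 0.01 + 0.004 * i) for i in range(12))
        events = (
            ("DYSPNOEA", 0.03),
            ("COUGH", 0.02),
            ("PALPITATIONS", 0.01),
            ("CHEST PAIN", 0.015),
        )
        effects = {
            ("DRUG_A", "DYSPNOEA"): 8.0,
            ("DRUG_A", "COUGH"): 4.0,
            ("DRUG_B", "DYSPNOEA"): 4.0,
            ("DRUG_B", "PALPITATIONS"): 3.0,
            ("DRUG_C", "CHEST PAIN"): 5.0,
            ("DRUG_D", "DYSPNOEA"): 2.0,
        }
        return cls(n_cases=20_000, drugs=drugs, events=events, effects=effects, seed=seed)

    @classmethod
    def from_toml(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from TOML (see README for the layout)."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        try:
            drugs = tuple((name, float(p)) for name, p in raw["drugs"].items())
            events = tuple((name, float(p)) for name, p in raw["events"].items())
        except KeyError as exc:
            raise ConfigError(f"simulate config: missing section {exc}") from exc
        effects = {
            (entry["drug"], entry["event"]): float(entry["rho"])
            for entry in raw.get("effects", [])
        }
        return cls(
            n_cases=int(raw.get("n_cases", 10_000)),
            drugs=drugs,
            events=events,
            effects=effects,
            duplicate_rate=float(raw.get("duplicate_rate", 0.1)),
            role_mix=dict(raw.get("role_mix", DEFAULT_ROLE_MIX)),
            seed=int(raw.get("seed", 0)),
        )


def single_signal_config(
    rho: float = 10.0,
    exposure: float = 0.05,
    background: float = 0.01,
    n_cases: int = 50_000,
    seed: int = 0,
) -> SyntheticConfig:
    """Parameter-recovery preset: one drug, one event, one planted odds ratio."""
    return SyntheticConfig(
        n_cases=n_cases,
        drugs=(("DRUG_A", exposure),),
        events=(("EVENT_X", background),),
        effects={("DRUG_A", "EVENT_X"): rho},
        duplicate_rate=0.0,
        seed=seed,
    )


def null_calibration_config(
    n_cases: int = 10_000,
    n_drugs: int = 30,
    n_events: int = 15,
    exposure: float = 0.03,
    background: float = 0.02,
    seed: int = 0,
) -> SyntheticConfig:
    """Type-I-error preset: every drug–event pair null (rho = 1)."""
    return SyntheticConfig(
        n_cases=n_cases,
        drugs=tuple((f"DRUG_{i:02d}", exposure) for i in range(n_drugs)),
        events=tuple((f"EVENT_{j:02d}", background) for j in range(n_events)),
        effects={},
        duplicate_rate=0.0,
        seed=seed,
    )


@dataclass
class GenerateResult:
    out_dir: Path
    files: list[Path]
    truth_path: Path
    n_cases: int
    n_duplicates: int


def _quarter_labels(dates: np.ndarray) -> np.ndarray:
    """YYQq labels (e.g. 18Q1) from an array of datetime64[D]."""
    strings = np.datetime_as_string(dates, unit="D")
    years = strings.astype("U4")
    months = np.char.replace(strings, "-", "").astype("U6")
    month_num = np.array([int(s[4:6]) for s in months])
    quarters = (month_num - 1) // 3 + 1
    return np.array([f"{y[2:]}Q{q}" for y, q in zip(years, quarters)])


def _dates_to_fda_dt(dates: np.ndarray) -> np.ndarray:
    return np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")


def generate(config: SyntheticConfig, out_dir: str | Path) -> GenerateResult:
    """Write one synthetic FAERS-dialect file set plus the truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n = config.n_cases
    drug_names = np.array([normalize_key(name) for name, _ in config.drugs])
    event_names = np.array([normalize_key(name) for name, _ in config.events])
    marginals = np.array([p for _, p in config.drugs])
    backgrounds = np.array([p for _, p in config.events])
    drug_index = {name: i for i, name in enumerate(drug_names)}
    event_index = {name: j for j, name in enumerate(event_names)}

    log_rho = np.zeros((len(drug_names), len(event_names)))
    for (drug, event), rho in config.effects.items():
        log_rho[drug_index[normalize_key(drug)], event_index[normalize_key(event)]] = math.log(rho)

    # exposures and event occurrences (odds-scale effect combination)
    exposed = rng.random((n, len(drug_names))) < marginals
    base_logit = np.log(backgrounds / (1.0 - backgrounds))
    logits = base_logit + exposed @ log_rho
    prob = 1.0 / (1.0 + np.exp(-logits))
    occurred = rng.random((n, len(event_names))) < prob

    # roles per drug mention
    case_idx, drug_idx = np.nonzero(exposed)
    roles_avail = sorted(config.role_mix)
    role_probs = np.array([config.role_mix[r] for r in roles_avail])
    mention_roles = rng.choice(np.array(roles_avail), size=len(case_idx), p=role_probs)

    # dates, duplicates
    day_offsets = rng.integers(0, _N_DAYS, size=n)
    dates = WINDOW_START + day_offsets.astype("timedelta64[D]")
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_delta = rng.integers(1, 91, size=n).astype("timedelta64[D]")
    dup_dates = np.minimum(dates + dup_delta, WINDOW_END)

    caseids = np.arange(1, n + 1)
    pid_v1 = caseids * 100 + 1
    pid_v2 = caseids * 100 + 2

    fda_v1 = _dates_to_fda_dt(dates)
    fda_v2 = _dates_to_fda_dt(dup_dates)
    quarter_v1 = _quarter_labels(dates)
    quarter_v2 = _quarter_labels(dup_dates)

    demo = pd.DataFrame(
        {
            "primaryid": np.concatenate([pid_v1, pid_v2[dup_mask]]),
            "caseid": np.concatenate([caseids, caseids[dup_mask]]),
            "caseversion": np.concatenate(
                [np.ones(n, dtype=int), np.full(int(dup_mask.sum()), 2)]
            ),
            "fda_dt": np.concatenate([fda_v1, fda_v2[dup_mask]]),
            "_quarter": np.concatenate([quarter_v1, quarter_v2[dup_mask]]),
        }
    )

    mention_dup = dup_mask[case_idx]
    drug = pd.DataFrame(
        {
            "primaryid": np.concatenate([pid_v1[case_idx], pid_v2[case_idx[mention_dup]]]),
            "drug_seq": np.concatenate([drug_idx + 1, drug_idx[mention_dup] + 1]),
            "drugname": np.concatenate(
                [drug_names[drug_idx], drug_names[drug_idx[mention_dup]]]
            ),
            "role_cod": np.concatenate([mention_roles, mention_roles[mention_dup]]),
            "_quarter": np.concatenate(
                [quarter_v1[case_idx], quarter_v2[case_idx[mention_dup]]]
            ),
        }
    )

    rcase_idx, event_idx = np.nonzero(occurred)
    reac_dup = dup_mask[rcase_idx]
    reac = pd.DataFrame(
        {
            "primaryid": np.concatenate([pid_v1[rcase_idx], pid_v2[rcase_idx[reac_dup]]]),
            "pt": np.concatenate([event_names[event_idx], event_names[event_idx[reac_dup]]]),
            "_quarter": np.concatenate(
                [quarter_v1[rcase_idx], quarter_v2[rcase_idx[reac_dup]]]
            ),
        }
    )

    files: list[Path] = []
    quarters = sorted(set(demo["_quarter"]))
    for table_name, frame, sort_cols in (
        ("DEMO", demo, ["primaryid"]),
        ("DRUG", drug, ["primaryid", "drug_seq"]),
        ("REAC", reac, ["primaryid", "pt"]),
    ):
        for quarter in quarters:
            part = (
                frame[frame["_quarter"] == quarter]
                .drop(columns="_quarter")
                .sort_values(sort_cols, kind="mergesort")
            )
            path = out_dir / f"{table_name}{quarter}.txt"
            part.to_csv(path, sep="$", index=False, lineterminator="\n")
            files.append(path)

    truth = pd.DataFrame(
        sorted(
            (normalize_key(drug_), normalize_key(event_), rho)
            for (drug_, event_), rho in config.effects.items()
        ),
        columns=["drug", "event", "rho"],
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")

    return GenerateResult(
        out_dir=out_dir,
        files=files,
        truth_path=truth_path,
        n_cases=n,
        n_duplicates=int(dup_mask.sum()),
    )


def sample_pair_tables(
    n_cases: int,
    exposure: float,
    background: float,
    rho: float,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw 2x2 tables (a,b,c,d) directly from the single-pair model.

    A fast closed-form sampler for calibration studies: exposure count is
    Binomial(n, exposure); events occur with background probability among
    the unexposed and with odds scaled by ``rho`` among the exposed.
    Returns an ``(n_reps, 4)`` integer array.
    """
    odds = background / (1.0 - background) * rho
    p_exposed = odds / (1.0 + odds)
    m = rng.binomial(n_cases, exposure, size=n_reps)
    a = rng.binomial(m, p_exposed)
    c = rng.binomial(n_cases - m, background)
    return np.column_stack([a, m - a, c, n_cases - m - c])
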