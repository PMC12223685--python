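"""Seeded synthetic cohorts of violent-death records.

Record-level narrative data from violent-death surveillance systems is
access-restricted: law-enforcement (LE) and coroner/medical-examiner (CME)
narratives may not leave approved environments.  This module generates
statistically controllable stand-in cohorts so that every downstream stage
of the classification-simulation pipeline (preprocessing, splitting,
training, subgroup evaluation) can be developed and tested openly.

The generator emulates the features the simulation design depends on:

* four imbalanced binary outcomes drawn independently at configurable
  prevalences (defaults 5.9% / 9.2% / 15.2% / 24.8%);
* a demographic mix over race/ethnicity and sex;
* right-skewed narrative lengths (log-normal per subgroup and narrative
  source, parameterized by median and interquartile range);
* subgroup-specific circumstances-known rates — when circumstances are
  unknown the LE narrative collapses to a short uninformative template;
* planted outcome signal: each positive record carries one of a small set
  of fixed multi-word signal phrases with probability ``signal_strength``,
  negatives leak the phrase with probability ``leak_rate``; phrases have
  abbreviated surface forms ("v", "s", "gsw", "leo", ...) emitted at
  ``abbrev_rate``; positives additionally carry weaker outcome-specific
  context tokens;
* optional planted subgroup bias: a degradation multiplier that shortens a
  subgroup's narratives and reduces its signal-phrase carriage.

Text is template-based by design — statistically controllable, not
linguistically realistic.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "OUTCOMES",
    "RACE_ETHNICITY",
    "SEX",
    "NarrativeRecord",
    "GeneratorConfig",
    "CohortSummary",
    "default_config",
    "load_config",
    "generate_cohort",
    "summarize_cohort",
    "cohort_to_dataframe",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cohort_jsonl",
    "read_cohort_jsonl",
    "cohort_digest",
    "SIGNAL_PHRASES",
    "CONTEXT_TOKENS",
]

OUTCOMES = (
    "drive_by",
    "legal_intervention",
    "nonfatal_others_shot",
    "injured_at_home",
)
RACE_ETHNICITY = ("aian_nh", "api_nh", "black_nh", "hispanic", "white_nh")
SEX = ("female", "male")

CSV_COLUMNS = [
    "record_id",
    "le_narrative",
    "cme_narrative",
    "sex",
    "race_ethnicity",
    "weapon_type",
    "manner",
    "circumstances_known",
    "outcome_drive_by",
    "outcome_legal_intervention",
    "outcome_nonfatal_others_shot",
    "outcome_injured_at_home",
]

# ---------------------------------------------------------------------------
# Text fixtures
# ---------------------------------------------------------------------------
# Each outcome has a small set of signal-phrase surface variants.  Every
# variant is a (expanded, abbreviated) pair; abbreviated forms differ from
# the expanded form only in tokens covered by the packaged default
# abbreviation map, so abbreviation expansion recovers the expanded surface.
SIGNAL_PHRASES: dict[str, tuple[tuple[str, str], ...]] = {
    "drive_by": (
        (
            "the victim was struck by gunfire from a passing vehicle",
            "the v was struck by gunfire from a passing vehicle",
        ),
        (
            "suspect fired shots from a moving car at the victim",
            "s fired shots from a moving car at the vic",
        ),
        (
            "occupants of a vehicle drove by and fired multiple rounds",
            "occupants of a vehicle drove by and fired multiple rounds",
        ),
        (
            "witnesses described a drive by shooting from a dark sedan",
            "witnesses described a drive by shooting from a dark sedan",
        ),
        (
            "shooters in a passing truck opened fire at the victim",
            "shooters in a passing truck opened fire at the v",
        ),
        (
            "a car slowed and its occupant opened fire from the window",
            "a car slowed and its occupant opened fire from the window",
        ),
    ),
    "legal_intervention": (
        (
            "the victim was shot by a law enforcement officer on scene",
            "the v was shot by a leo on scene",
        ),
        (
            "officers discharged their duty weapons striking the suspect",
            "ofc discharged their duty weapons striking the s",
        ),
        (
            "police department units responded and an officer fired",
            "pd units responded and an ofc fired",
        ),
        (
            "the subject was fatally shot during an officer involved shooting",
            "the subject was fatally shot during an ofc involved shooting",
        ),
        (
            "officers returned fire striking the suspect multiple times",
            "officers returned fire striking the sus multiple times",
        ),
        (
            "the decedent was killed during an encounter with law enforcement",
            "the decedent was killed during an encounter with le",
        ),
    ),
    "nonfatal_others_shot": (
        (
            "a second victim sustained a nonfatal gunshot wound",
            "a second vic sustained a nonfatal gsw",
        ),
        (
            "two other people were shot and survived their injuries",
            "two other people were shot and survived their injuries",
        ),
        (
            "additional victims were transported with gunshot wounds and survived",
            "additional victims were transported with gsws and survived",
        ),
        (
            "another person was wounded by gunfire but survived",
            "another person was wounded by gunfire but survived",
        ),
        (
            "several bystanders suffered gunshot wounds and were treated",
            "several bystanders suffered gsws and were treated",
        ),
        (
            "one more victim was hit by a bullet and recovered",
            "one more vic was hit by a bullet and recovered",
        ),
    ),
    "injured_at_home": (
        (
            "the victim was found shot inside the residence",
            "the v was found shot inside the residence",
        ),
        (
            "the shooting occurred in the bedroom of the home",
            "the shooting occurred in the bedroom of the home",
        ),
        (
            "the victim was shot at home in the living room",
            "the vic was shot at home in the living room",
        ),
        (
            "gunfire erupted inside the apartment where the victim lived",
            "gunfire erupted inside the apartment where the v lived",
        ),
        (
            "the victim collapsed inside the house after being shot",
            "the v collapsed inside the house after being shot",
        ),
        (
            "the homicide took place in the dwelling where the victim resided",
            "the homicide took place in the dwelling where the v resided",
        ),
    ),
}

# Weaker outcome-correlated vocabulary.  Positive records sprinkle a few of
# these tokens into the narrative; the same tokens also sit in the filler
# pool so negatives carry them at a background rate.  They make positive
# records without a signal phrase partially recoverable, at the cost of
# training data.
CONTEXT_TOKENS: dict[str, tuple[str, ...]] = {
    "drive_by": (
        "retaliation", "gang", "corner", "casings", "intersection",
        "block", "cruising", "taillights", "curbside", "alley",
        "curfew", "graffiti", "hoodie", "revving", "swerved", "idling",
    ),
    "legal_intervention": (
        "commands", "taser", "bodycam", "standoff", "warrant",
        "pursuit", "backup", "holster", "dispatch", "perimeter",
        "negotiator", "ricochet", "vest", "sirens", "barricade", "custody",
    ),
    "nonfatal_others_shot": (
        "bystander", "crossfire", "crowd", "party", "stable",
        "graze", "triage", "ambulances", "panicked", "gathering",
        "stampede", "vigil", "fundraiser", "tourniquet", "stretcher", "chaos",
    ),
    "injured_at_home": (
        "kitchen", "domestic", "doorway", "couch", "hallway",
        "porch", "bedside", "landlord", "roommate", "upstairs",
        "mortgage", "backyard", "garage", "mailbox", "tenant", "basement",
    ),
}

_N_CONTEXT_SLOTS = 12

# Generic abstractor-report vocabulary used to pad narratives to their target
# length.  Deliberately excludes the distinctive content words of the signal
# phrases above; context tokens are appended so they occur in negatives too.
_FILLER_WORDS = (
    "the decedent was located unresponsive and pronounced dead after arrival "
    "officers responded to a report of gunshots heard in the area a caller "
    "stated that an unknown individual fled on foot prior to arrival the scene "
    "was secured and detectives canvassed for evidence investigators collected "
    "several items and interviewed neighbors family members stated the decedent "
    "had been involved in an earlier dispute the medical examiner performed an "
    "autopsy and the cause of death was determined the toxicology report was "
    "pending at the time of abstraction emergency personnel attempted life "
    "saving measures without success the incident remains under investigation "
    "no arrests had been made at the time of this report a firearm was "
    "recovered near the location surveillance footage was requested from a "
    "nearby business the victim had last been seen that evening relatives were "
    "notified by the coroner office records indicate prior contacts with the "
    "decedent statements were taken from those present the case was referred "
    "to the homicide unit for follow up a witness heard arguing before the "
    "incident the decedent history included prior injuries documentation was "
    "obtained from responding agencies the time of injury could not be "
    "confirmed officials noted inconsistencies between accounts the narrative "
    "was abstracted from available reports findings were consistent with the "
    "reported manner projectiles were submitted for analysis the firearm make "
    "and model were unknown the examination noted entry and exit sites "
    "clothing was collected as evidence the decedent identification was "
    "confirmed by family next of kin were present during notification"
).split()

_FILLER_VOCAB = tuple(dict.fromkeys(_FILLER_WORDS)) + tuple(
    tok for toks in CONTEXT_TOKENS.values() for tok in toks
)

# Filler words follow a Zipfian frequency profile, as natural text does:
# a handful of very common tokens appear in almost every narrative (and so
# carry no class information), with a long tail of rarer ones.  Context
# tokens sit in the tail so their background presence rate in a ~100-word
# negative narrative stays well below their planted rate in positives.
_ZIPF_EXPONENT = 1.0
_CONTEXT_FILLER_WEIGHT = 1.0 / 300.0

_UNINFORMATIVE_TEMPLATES = (
    "circumstances of the shooting are unknown pending investigation",
    "no further information was available at the time of abstraction",
    "limited details were reported by responding officers",
)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class NarrativeRecord:
    """One synthetic violent-death record."""

    record_id: str
    le_narrative: str
    cme_narrative: str
    sex: str
    race_ethnicity: str
    weapon_type: str
    manner: str
    circumstances_known: bool
    outcomes: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.sex not in SEX:
            raise ValueError(f"unknown sex category: {self.sex!r}")
        if self.race_ethnicity not in RACE_ETHNICITY:
            raise ValueError(f"unknown race/ethnicity category: {self.race_ethnicity!r}")
        for name, val in self.outcomes.items():
            if val not in (0, 1):
                raise ValueError(f"outcome {name!r} must be 0/1, got {val!r}")


@dataclass(frozen=True)
class LengthParams:
    """Median and IQR width (words) for LE and CME narratives of a subgroup."""

    median_le: float
    iqr_le: float
    median_cme: float
    iqr_cme: float


@dataclass
class GeneratorConfig:
    """All distributional knobs of the synthetic cohort generator.

    ``signal_strength`` is the probability that a positive record carries
    its outcome's signal phrase; ``leak_rate`` the probability a negative
    does.  ``abbrev_rate`` is the probability a planted phrase uses its
    abbreviated surface form.  ``context_rate`` governs the weaker
    outcome-context tokens planted into positives.  ``bias_knobs`` maps a
    subgroup category value (e.g. ``"black_nh"`` or ``"female"``) to a
    multiplier in (0, 1] applied to that subgroup's narrative-length
    medians and signal-phrase carriage; 1.0 means no degradation.
    """

    n_records: int
    prevalence: dict[str, float]
    subgroup_mix: dict[tuple[str, str], float]
    length_params: dict[str, LengthParams]
    circumstances_known_rate: dict[str, float]
    signal_strength: float = 0.9
    leak_rate: float = 0.05
    abbrev_rate: float = 0.3
    context_rate: float = 0.7
    bias_knobs: dict[str, float] = field(default_factory=dict)
    uninformative_cap: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        for name in self.prevalence:
            if name not in OUTCOMES:
                raise ValueError(f"unknown outcome name in prevalence map: {name!r}")
        for name, p in self.prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence[{name!r}] must be in (0,1)")
        total = sum(self.subgroup_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subgroup_mix must sum to 1, got {total}")
        for (race, sex) in self.subgroup_mix:
            if race not in RACE_ETHNICITY or sex not in SEX:
                raise ValueError(f"unknown subgroup key: {(race, sex)!r}")
        for frac_name in ("signal_strength", "leak_rate", "abbrev_rate", "context_rate"):
            val = getattr(self, frac_name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{frac_name} must be in [0,1]")
        for key, rate in self.circumstances_known_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"circumstances_known_rate[{key!r}] must be in [0,1]")
        for key, mult in self.bias_knobs.items():
            if not 0.0 < mult <= 1.0:
                raise ValueError(f"bias_knobs[{key!r}] must be in (0,1]")
        if self.signal_strength <= self.leak_rate:
            warnings.warn(
                "signal_strength <= leak_rate: classification tasks on this "
                "cohort are not learnable",
                UserWarning,
                stacklevel=2,
            )


def default_config(n_records: int = 20000, seed: int = 20150) -> GeneratorConfig:
    """Packaged default configuration.

    Prevalences, subgroup composition, narrative-length medians/IQRs and
    circumstances-known rates follow published descriptive statistics for
    firearm homicides in the US violent-death surveillance system
    (2015-2020).  See ``narrsim/data/default_generator.yaml``.
    """
    with resources.files("narrsim.data").joinpath("default_generator.yaml").open() as fh:
        cfg = load_config(fh)
    cfg.n_records = n_records
    cfg.seed = seed
    return cfg


def load_config(stream) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML document.

    ``subgroup_mix`` may be given directly (keys ``"race|sex"``) or as
    ``race_marginal`` and ``sex_marginal`` blocks, in which case the mix is
    the normalized outer product of the two marginals.
    """
    doc = yaml.safe_load(stream)
    if "subgroup_mix" in doc:
        mix = {
            tuple(key.split("|")): float(v) for key, v in doc["subgroup_mix"].items()
        }
    else:
        race = doc["race_marginal"]
        sex = doc["sex_marginal"]
        raw = {
            (r, s): float(race[r]) * float(sex[s]) for r in race for s in sex
        }
        z = sum(raw.values())
        mix = {k: v / z for k, v in raw.items()}
    length_params = {
        key: LengthParams(
            median_le=float(v["median_le"]),
            iqr_le=float(v["iqr_le"]),
            median_cme=float(v["median_cme"]),
            iqr_cme=float(v["iqr_cme"]),
        )
        for key, v in doc["length_params"].items()
    }
    cfg = GeneratorConfig(
        n_records=int(doc.get("n_records", 20000)),
        prevalence={k: float(v) for k, v in doc["prevalence"].items()},
        subgroup_mix=mix,
        length_params=length_params,
        circumstances_known_rate={
            k: float(v) for k, v in doc["circumstances_known_rate"].items()
        },
        signal_strength=float(doc.get("signal_strength", 0.9)),
        leak_rate=float(doc.get("leak_rate", 0.05)),
        abbrev_rate=float(doc.get("abbrev_rate", 0.3)),
        context_rate=float(doc.get("context_rate", 0.7)),
        bias_knobs={k: float(v) for k, v in doc.get("bias_knobs", {}).items()},
        uninformative_cap=int(doc.get("uninformative_cap", 15)),
        seed=int(doc.get("seed", 0)),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------
def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    # Match a log-normal to (median, IQR width): the quartiles sit at
    # exp(mu +/- z75*sigma), so IQR/median = 2*sinh(z75*sigma).
    z75 = 0.6744897501960817
    mu = math.log(median)
    sigma = math.asinh(iqr / (2.0 * median)) / z75
    return mu, sigma


def _bias_multiplier(config: GeneratorConfig, race: str, sex: str) -> float:
    return config.bias_knobs.get(race, 1.0) * config.bias_knobs.get(sex, 1.0)


def _draw_length(rng: np.random.Generator, median: float, iqr: float, mult: float) -> int:
    # degradation scales the whole length distribution (median and IQR
    # alike), leaving its shape on the log scale unchanged
    mu, sigma = _lognormal_params(max(1.0, median * mult), max(1.0, iqr * mult))
    return max(1, round(float(rng.lognormal(mu, sigma))))


def _compose(
    rng: np.random.Generator,
    target_len: int,
    chunks: Sequence[Sequence[str]],
    singles: Sequence[str],
    intro: Sequence[str],
) -> str:
    """Assemble a narrative of ~target_len whitespace tokens.

    The intro sentence, signal-phrase chunks (kept contiguous) and single
    context tokens replace filler rather than extending the text, so the
    length distribution is unaffected by outcome status.
    """
    fixed = len(intro) + sum(len(c) for c in chunks) + len(singles)
    n_fill = max(0, target_len - fixed)
    body: list[str] = (
        list(rng.choice(_FILLER_VOCAB_ARR, size=n_fill, p=_FILLER_PROBS))
        if n_fill
        else []
    )
    for tok in singles:
        pos = int(rng.integers(0, len(body) + 1))
        body.insert(pos, tok)
    segments: list[list[str]] = [body]
    for chunk in chunks:
        seg = segments[int(rng.integers(0, len(segments)))]
        pos = int(rng.integers(0, len(seg) + 1))
        seg[pos:pos] = list(chunk)
    return " ".join(list(intro) + [t for seg in segments for t in seg])


_FILLER_VOCAB_ARR = np.array(_FILLER_VOCAB)
_context_set = {tok for toks in CONTEXT_TOKENS.values() for tok in toks}
_FILLER_PROBS = np.array(
    [
        _CONTEXT_FILLER_WEIGHT
        if w in _context_set
        else 1.0 / (rank + 1.0) ** _ZIPF_EXPONENT
        for rank, w in enumerate(_FILLER_VOCAB)
    ]
)
_FILLER_PROBS = _FILLER_PROBS / _FILLER_PROBS.sum()


def _draw_phrase(rng: np.random.Generator, outcome: str, abbrev_rate: float) -> list[str]:
    expanded, abbreviated = SIGNAL_PHRASES[outcome][
        int(rng.integers(0, len(SIGNAL_PHRASES[outcome])))
    ]
    phrase = abbreviated if rng.random() < abbrev_rate else expanded
    return phrase.split()


def generate_cohort(config: GeneratorConfig) -> list[NarrativeRecord]:
    """Generate a seeded synthetic cohort.

    Deterministic for a given config (including seed): each record draws
    from its own child RNG stream derived from the root seed, so cohorts
    are reproducible and stable under partial regeneration.
    """
    config.validate()
    outcome_names = [o for o in OUTCOMES if o in config.prevalence]
    mix_keys = sorted(config.subgroup_mix)
    mix_probs = np.array([config.subgroup_mix[k] for k in mix_keys], dtype=float)
    mix_probs = mix_probs / mix_probs.sum()
    mix_cum = np.cumsum(mix_probs)

    overall_len = config.length_params.get("overall")
    records: list[NarrativeRecord] = []
    root = np.random.SeedSequence(config.seed)
    for i, child in enumerate(root.spawn(config.n_records)):
        rng = np.random.default_rng(child)
        idx = min(int(np.searchsorted(mix_cum, rng.random(), side="right")), len(mix_keys) - 1)
        race, sex = mix_keys[idx]
        mult = _bias_multiplier(config, race, sex)
        outcomes = {
            name: int(rng.random() < config.prevalence[name]) for name in outcome_names
        }
        ck_rate = config.circumstances_known_rate.get(
            race, config.circumstances_known_rate.get("overall", 0.758)
        )
        circumstances_known = bool(rng.random() < ck_rate)

        lp = config.length_params.get(race, overall_len)
        if lp is None:
            raise ValueError(f"no length_params for subgroup {race!r} and no 'overall' fallback")
        len_le = _draw_length(rng, lp.median_le, lp.iqr_le, mult)
        len_cme = _draw_length(rng, lp.median_cme, lp.iqr_cme, mult)

        le_chunks: list[list[str]] = []
        cme_chunks: list[list[str]] = []
        le_singles: list[str] = []
        cme_singles: list[str] = []
        for name in outcome_names:
            positive = outcomes[name] == 1
            carry_p = config.signal_strength * mult if positive else config.leak_rate
            if rng.random() < carry_p:
                # The two report sources describe the same event in their own
                # words: each draws its surface variant independently.
                if circumstances_known:
                    le_chunks.append(_draw_phrase(rng, name, config.abbrev_rate))
                cme_chunks.append(_draw_phrase(rng, name, config.abbrev_rate))
            if positive:
                ctx = CONTEXT_TOKENS[name]
                for _ in range(_N_CONTEXT_SLOTS):
                    # the degradation multiplier thins the whole planted
                    # outcome signal, context tokens included
                    if rng.random() < config.context_rate * mult:
                        tok = ctx[int(rng.integers(0, len(ctx)))]
                        (le_singles if circumstances_known else cme_singles).append(tok)

        age = int(rng.integers(16, 75))
        intro = ["the", "victim", "was", "a", str(age), "year", "old", sex + "."]
        if circumstances_known:
            le_text = _compose(rng, len_le, le_chunks, le_singles, intro)
        else:
            le_text = _UNINFORMATIVE_TEMPLATES[
                int(rng.integers(0, len(_UNINFORMATIVE_TEMPLATES)))
            ]
        cme_text = _compose(rng, len_cme, cme_chunks, cme_singles, intro)

        records.append(
            NarrativeRecord(
                record_id=f"rec-{i:06d}",
                le_narrative=le_text,
                cme_narrative=cme_text,
                sex=sex,
                race_ethnicity=race,
                weapon_type="firearm",
                manner="homicide",
                circumstances_known=circumstances_known,
                outcomes=outcomes,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------
@dataclass
class SubgroupSummary:
    n: int
    median_words_le: float
    iqr_words_le: tuple[float, float]
    median_words_cme: float
    iqr_words_cme: tuple[float, float]
    circumstances_known_rate: float


@dataclass
class CohortSummary:
    n: int
    prevalence: dict[str, float]
    by_race_ethnicity: dict[str, SubgroupSummary]
    by_sex: dict[str, SubgroupSummary]
    overall: SubgroupSummary


def _word_count(text: str) -> int:
    return len(text.split())


def _summarize_group(records: Sequence[NarrativeRecord]) -> SubgroupSummary:
    le = np.array([_word_count(r.le_narrative) for r in records])
    cme = np.array([_word_count(r.cme_narrative) for r in records])
    ck = np.array([r.circumstances_known for r in records])
    return SubgroupSummary(
        n=len(records),
        median_words_le=float(np.median(le)),
        iqr_words_le=(float(np.percentile(le, 25)), float(np.percentile(le, 75))),
        median_words_cme=float(np.median(cme)),
        iqr_words_cme=(float(np.percentile(cme, 25)), float(np.percentile(cme, 75))),
        circumstances_known_rate=float(ck.mean()),
    )


def summarize_cohort(records: Sequence[NarrativeRecord]) -> CohortSummary:
    """Descriptive statistics of a cohort.

    Word counts are whitespace-token counts of the raw narrative text.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    outcome_names = sorted({name for r in records for name in r.outcomes})
    prevalence = {
        name: float(np.mean([r.outcomes.get(name, 0) for r in records]))
        for name in outcome_names
    }
    by_race = {
        race: _summarize_group(group)
        for race in RACE_ETHNICITY
        if (group := [r for r in records if r.race_ethnicity == race])
    }
    by_sex = {
        sex: _summarize_group(group)
        for sex in SEX
        if (group := [r for r in records if r.sex == sex])
    }
    return CohortSummary(
        n=len(records),
        prevalence=prevalence,
        by_race_ethnicity=by_race,
        by_sex=by_sex,
        overall=_summarize_group(records),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------
def _record_to_row(r: NarrativeRecord) -> dict:
    row = {
        "record_id": r.record_id,
        "le_narrative": r.le_narrative,
        "cme_narrative": r.cme_narrative,
        "sex": r.sex,
        "race_ethnicity": r.race_ethnicity,
        "weapon_type": r.weapon_type,
        "manner": r.manner,
        "circumstances_known": r.circumstances_known,
    }
    for name in OUTCOMES:
        row[f"outcome_{name}"] = int(r.outcomes.get(name, 0))
    return row


def _row_to_record(row: Mapping) -> NarrativeRecord:
    ck = row["circumstances_known"]
    if isinstance(ck, str):
        ck = ck.strip().lower() in ("true", "1", "yes")
    return NarrativeRecord(
        record_id=str(row["record_id"]),
        le_narrative=str(row["le_narrative"]),
        cme_narrative=str(row["cme_narrative"]),
        sex=str(row["sex"]),
        race_ethnicity=str(row["race_ethnicity"]),
        weapon_type=str(row["weapon_type"]),
        manner=str(row["manner"]),
        circumstances_known=bool(ck),
        outcomes={name: int(row[f"outcome_{name}"]) for name in OUTCOMES},
    )


def cohort_to_dataframe(records: Iterable[NarrativeRecord]):
    import pandas as pd

    return pd.DataFrame([_record_to_row(r) for r in records], columns=CSV_COLUMNS)


def write_cohort_csv(records: Iterable[NarrativeRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, quoting=csv.QUOTE_NONNUMERIC)
        writer.writeheader()
        for r in records:
            row = _record_to_row(r)
            row["circumstances_known"] = "true" if row["circumstances_known"] else "false"
            writer.writerow(row)


def read_cohort_csv(path) -> list[NarrativeRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        records = [_row_to_record(row) for row in reader]
    _check_unique_ids(records)
    return records


def write_cohort_jsonl(records: Iterable[NarrativeRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            row = _record_to_row(r)
            fh.write(json.dumps(row, sort_keys=False) + "\n")


def read_cohort_jsonl(path) -> list[NarrativeRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(_row_to_record(json.loads(line)))
    _check_unique_ids(records)
    return records


def _check_unique_ids(records: Sequence[NarrativeRecord]) -> None:
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record_id in cohort")


def cohort_digest(records: Iterable[NarrativeRecord]) -> str:
    """SHA-256 of the serialized cohort (used for manifest provenance)."""
    buf = io.StringIO()
    for r in records:
        buf.write(json.dumps(_record_to_row(r), sort_keys=True))
        buf.write("\n")
    return hashlib.sha256(buf.getvalue().encode("utf-8")).hexdigest()
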