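"""Synthetic cohort generator: reproducibility, marginal recovery,
planted-signal limits and serialization."""

import json

import numpy as np
import pytest
from scipy import stats

from narrsim.synthetic import (
    CONTEXT_TOKENS,
    OUTCOMES,
    SIGNAL_PHRASES,
    GeneratorConfig,
    LengthParams,
    NarrativeRecord,
    cohort_digest,
    default_config,
    generate_cohort,
    read_cohort_csv,
    read_cohort_jsonl,
    summarize_cohort,
    write_cohort_csv,
    write_cohort_jsonl,
)


def tiny_config(**overrides):
    cfg = default_config(n_records=50, seed=3)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


class TestGenerateCohort:
    def test_reproducible_byte_identical(self):
        cfg = default_config(n_records=300, seed=11)
        a = generate_cohort(cfg)
        b = generate_cohort(default_config(n_records=300, seed=11))
        assert cohort_digest(a) == cohort_digest(b)

    def test_different_seeds_differ(self):
        a = generate_cohort(default_config(n_records=300, seed=1))
        b = generate_cohort(default_config(n_records=300, seed=2))
        assert cohort_digest(a) != cohort_digest(b)

    def test_record_count_and_unique_ids(self):
        records = generate_cohort(default_config(n_records=500, seed=5))
        assert len(records) == 500
        assert len({r.record_id for r in records}) == 500

    def test_prevalence_within_binomial_interval(self):
        # exact binomial 95% interval at n=10000, p=0.059 is [0.054, 0.064]
        cfg = default_config(n_records=10000, seed=7)
        records = generate_cohort(cfg)
        frac = np.mean([r.outcomes["legal_intervention"] for r in records])
        assert 0.054 <= frac <= 0.064

    def test_signal_phrase_deterministic_limits(self):
        # signal 1 / leak 0 / abbrev 0: every positive text carries the
        # expanded phrase, no negative does
        cfg = tiny_config(signal_strength=1.0, leak_rate=0.0, abbrev_rate=0.0)
        cfg.prevalence = {"drive_by": 0.4}
        records = generate_cohort(cfg)
        expanded = [pair[0] for pair in SIGNAL_PHRASES["drive_by"]]
        for r in records:
            combined = r.le_narrative + " " + r.cme_narrative
            carries = any(p in combined for p in expanded)
            assert carries == bool(r.outcomes["drive_by"])

    def test_uninformative_narrative_capped(self):
        cfg = default_config(n_records=400, seed=13)
        records = generate_cohort(cfg)
        unknown = [r for r in records if not r.circumstances_known]
        assert unknown, "expected some circumstances-unknown records"
        for r in unknown:
            assert len(r.le_narrative.split()) <= cfg.uninformative_cap

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (dict(n_records=0), "n_records"),
            (dict(prevalence={"not_an_outcome": 0.1}), "unknown outcome"),
            (dict(subgroup_mix={("black_nh", "male"): 0.5}), "sum to 1"),
            (dict(signal_strength=1.5), "signal_strength"),
        ],
    )
    def test_invalid_config_rejected(self, mutate, match):
        cfg = default_config(n_records=10, seed=1)
        for key, val in mutate.items():
            setattr(cfg, key, val)
        with pytest.raises(ValueError, match=match):
            generate_cohort(cfg)

    def test_unlearnable_config_warns(self):
        cfg = tiny_config(signal_strength=0.05, leak_rate=0.5)
        with pytest.warns(UserWarning, match="not learnable"):
            cfg.validate()

    def test_bias_knob_monotonicity(self):
        # increasing degradation never lengthens narratives or raises
        # signal-phrase carriage for the degraded subgroup
        phrases = [p for pair in SIGNAL_PHRASES["drive_by"] for p in pair]
        mean_len, carriage = [], []
        for mult in (1.0, 0.75, 0.5, 0.25):
            cfg = default_config(n_records=3000, seed=17)
            cfg.prevalence = {"drive_by": 0.3}
            cfg.bias_knobs = {"black_nh": mult}
            records = [
                r for r in generate_cohort(cfg) if r.race_ethnicity == "black_nh"
            ]
            known = [r for r in records if r.circumstances_known]
            mean_len.append(np.mean([len(r.le_narrative.split()) for r in known]))
            pos = [r for r in records if r.outcomes["drive_by"] == 1]
            carriage.append(
                np.mean(
                    [
                        any(
                            p in (r.le_narrative + " " + r.cme_narrative)
                            for p in phrases
                        )
                        for r in pos
                    ]
                )
            )
        assert all(a >= b for a, b in zip(mean_len, mean_len[1:]))
        assert all(a >= b for a, b in zip(carriage, carriage[1:]))


class TestCalibration:
    """Marginal recovery at the packaged default calibration, n=20000."""

    def test_prevalences(self, calibrated_cohort):
        cfg = default_config()
        n = len(calibrated_cohort)
        for name, p in cfg.prevalence.items():
            count = sum(r.outcomes[name] for r in calibrated_cohort)
            lo = stats.binom.ppf(0.005, n, p)
            hi = stats.binom.ppf(0.995, n, p)
            assert lo <= count <= hi, name

    def test_subgroup_mix(self, calibrated_cohort):
        cfg = default_config()
        n = len(calibrated_cohort)
        for (race, sex), p in cfg.subgroup_mix.items():
            count = sum(
                1
                for r in calibrated_cohort
                if r.race_ethnicity == race and r.sex == sex
            )
            lo = stats.binom.ppf(0.005, n, p)
            hi = stats.binom.ppf(0.995, n, p)
            assert lo <= count <= hi, (race, sex)

    def test_circumstances_known_rates(self, calibrated_cohort):
        cfg = default_config()
        summary = summarize_cohort(calibrated_cohort)
        for race, group in summary.by_race_ethnicity.items():
            p = cfg.circumstances_known_rate[race]
            count = round(group.circumstances_known_rate * group.n)
            lo = stats.binom.ppf(0.005, group.n, p)
            hi = stats.binom.ppf(0.995, group.n, p)
            assert lo <= count <= hi, race

    def test_narrative_medians(self, calibrated_cohort):
        # LE medians parameterize the informative (circumstances-known)
        # narratives; CME narratives are never truncated
        cfg = default_config()
        known = [r for r in calibrated_cohort if r.circumstances_known]
        summary_known = summarize_cohort(known)
        summary_all = summarize_cohort(calibrated_cohort)
        for race, lp in cfg.length_params.items():
            got_le = summary_known.by_race_ethnicity[race].median_words_le
            got_cme = summary_all.by_race_ethnicity[race].median_words_cme
            assert abs(got_le - lp.median_le) <= 0.10 * lp.median_le, race
            assert abs(got_cme - lp.median_cme) <= 0.10 * lp.median_cme, race


class TestSummarize:
    def test_median_of_two_records(self):
        base = dict(
            cme_narrative="x",
            sex="male",
            race_ethnicity="black_nh",
            weapon_type="firearm",
            manner="homicide",
            circumstances_known=True,
            outcomes={"drive_by": 0},
        )
        records = [
            NarrativeRecord(record_id="a", le_narrative="one two three", **base),
            NarrativeRecord(
                record_id="b", le_narrative="one two three four five", **base
            ),
        ]
        assert summarize_cohort(records).overall.median_words_le == 4.0

    def test_zero_prevalence(self, small_cohort):
        records = [r for r in small_cohort if r.outcomes["drive_by"] == 0]
        assert summarize_cohort(records).prevalence["drive_by"] == 0.0

    def test_counts_partition_cohort(self, small_cohort):
        summary = summarize_cohort(small_cohort)
        assert sum(g.n for g in summary.by_race_ethnicity.values()) == summary.n
        assert sum(g.n for g in summary.by_sex.values()) == summary.n

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort([])


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(small_cohort[:100], path)
        back = read_cohort_csv(path)
        assert cohort_digest(back) == cohort_digest(small_cohort[:100])

    def test_jsonl_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.jsonl"
        write_cohort_jsonl(small_cohort[:100], path)
        back = read_cohort_jsonl(path)
        assert cohort_digest(back) == cohort_digest(small_cohort[:100])

    def test_csv_column_order(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(small_cohort[:5], path)
        header = path.read_text(encoding="utf-8").splitlines()[0]
        assert header.replace('"', "").split(",") == [
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
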