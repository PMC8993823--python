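"""Species-shaped fixtures and pseudo-observed datasets with known truth.

The five fixtures mirror the study system's CNN datasets: diploid
individuals per lineage, SNP count, realized genotype missingness, the
literature mutation rate (plants 7e-9, animals 2.8e-9 substitutions per
site per generation) and generation time.  Pseudo-observed datasets are
simulated under a known parameter draw so that every downstream stage
(classification, calibration, ABC, parameter recovery) can be validated
end-to-end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr

from .demography import DemographyParams, PriorSet, ScenarioId, default_priors, draw_parameters
from .cnn_abc import (
    TrainingSpec,
    abc_estimate_parameters,
    abc_select_model,
    calibrate_temperature,
    evaluate_classifier,
    predict_probabilities,
    train_classifier,
    train_regressor,
)
from .encoding import encode_image
from .simulate import (
    GenotypeMatrix,
    ReferenceTable,
    SampleConfig,
    build_reference_table,
    inject_missingness,
    simulate_genotypes,
)

__all__ = [
    "SpeciesFixture",
    "species_fixtures",
    "make_pseudo_observed",
    "recovery_experiment",
]

MU_PLANT = 7e-9
MU_ANIMAL = 2.8e-9


@dataclass(frozen=True)
class SpeciesFixture:
    """Shape of one species' CNN dataset: counts, SNPs, missingness, rates."""

    name: str
    n_ind_ez: int
    n_ind_z: int
    n_snps: int
    missing_fraction: float
    mu: float
    gen_times: tuple[float, ...]  # first entry is the default

    def sample_config(
        self,
        scale: float = 1.0,
        gen_time: float | None = None,
        n_loci: int | None = None,
        snp_mode: str = "calibrated",
    ) -> SampleConfig:
        """SampleConfig at a fraction of the fixture's SNP count.

        ``scale`` rescales the SNP columns (the CNN width); individual counts
        are kept so the dataset's row structure stays recognizable.
        """
        if not 0 < scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        target = max(1, int(round(scale * self.n_snps)))
        return SampleConfig(
            n_ind_ez=self.n_ind_ez,
            n_ind_z=self.n_ind_z,
            n_loci=n_loci if n_loci is not None else 10 * target,
            target_snps=target,
            missing_fraction=self.missing_fraction,
            mu=self.mu,
            gen_time_years=gen_time if gen_time is not None else self.gen_times[0],
            snp_mode=snp_mode,
        )


_FIXTURES = (
    SpeciesFixture("E. seguieriana", 80, 135, 12125, 0.15, MU_PLANT, (10.0,)),
    SpeciesFixture("O. petraeus", 10, 10, 1763, 0.42, MU_ANIMAL, (1.0,)),
    SpeciesFixture("P. taurica", 23, 22, 12542, 0.17, MU_ANIMAL, (3.0, 10.0)),
    SpeciesFixture("S. nigromaculatus", 12, 6, 2922, 0.41, MU_ANIMAL, (1.0,)),
    SpeciesFixture("S. capillata", 102, 98, 3813, 0.27, MU_PLANT, (25.0,)),
)


def species_fixtures() -> dict[str, SpeciesFixture]:
    """The five species fixtures, keyed by name."""
    return {f.name: f for f in _FIXTURES}


def make_pseudo_observed(
    scenario: ScenarioId,
    fixture: SpeciesFixture,
    scale: float,
    seed: int,
    priors: PriorSet | None = None,
) -> tuple[DemographyParams, GenotypeMatrix]:
    """Simulate one dataset of known truth at the fixture's shape.

    The truth draw, the coalescent simulation and the missingness mask each
    use a private stream spawned from ``seed``, disjoint from any reference
    table built from a different master seed.
    """
    priors = priors or default_priors()
    config = fixture.sample_config(scale=scale)
    # namespace 1 keeps truth streams disjoint from reference tables built
    # with the same master seed (namespace 0)
    s_draw, s_sim, s_miss = (
        int(s) for s in np.random.SeedSequence([seed, 1]).generate_state(3, dtype=np.uint64)
    )
    truth = draw_parameters(priors, scenario, s_draw)
    gm = simulate_genotypes(truth, config, s_sim)
    gm = inject_missingness(gm, config.missing_fraction, s_miss)
    return truth, gm


def classification_run(
    config: SampleConfig,
    n_train_per_scenario: int,
    n_val_per_scenario: int,
    n_test_per_scenario: int,
    seed: int,
    hyper: TrainingSpec | None = None,
    priors: PriorSet | None = None,
) -> dict:
    """Simulate balanced reference sets, train + calibrate the CNN, and
    evaluate held-out scenario-classification accuracy.

    Returns the trained model, the calibration result, the held-out test
    table and the evaluation (confusion matrix and accuracies).
    """
    priors = priors or default_priors()
    scenarios = list(ScenarioId)
    master = np.random.SeedSequence([seed, 2])
    s_table, s_train, s_test = (int(s) for s in master.generate_state(3, dtype=np.uint32))
    table = build_reference_table(
        scenarios, priors, n_train_per_scenario + n_val_per_scenario, config, seed=s_table
    )
    train_idx, val_idx = [], []
    for scen in scenarios:
        idx = np.flatnonzero(table.labels == int(scen))
        train_idx.append(idx[:n_train_per_scenario])
        val_idx.append(idx[n_train_per_scenario:])
    train = table.subset(np.concatenate(train_idx))
    val = table.subset(np.concatenate(val_idx))
    model = train_classifier(train, val, hyper=hyper, seed=s_train)
    calib = calibrate_temperature(model, val)
    test = build_reference_table(scenarios, priors, n_test_per_scenario, config, seed=s_test)
    evaluation = evaluate_classifier(model, calib.temperature, test)
    return {
        "model": model,
        "calibration": calib,
        "train": train,
        "val": val,
        "test": test,
        "evaluation": evaluation,
    }


def recovery_experiment(
    fixture: SpeciesFixture,
    scale: float,
    n_train_per_scenario: int,
    n_test: int,
    seed: int,
    hyper: TrainingSpec | None = None,
    val_fraction: float = 0.15,
    abc_tolerance: float = 0.1,
    n_pseudo_observed: int = 20,
    pseudo_scenario: ScenarioId = ScenarioId.PARALLEL_EXPANSION,
    priors: PriorSet | None = None,
) -> dict:
    """End-to-end simulation study at desk scale.

    Builds a balanced reference table, trains and calibrates the classifier,
    measures held-out accuracy, runs scenario selection and parameter ABC on
    pseudo-observed datasets of known truth, and reports accuracy, the
    confusion matrix, per-dataset scenario posterior probabilities, Spearman
    correlations between truth and posterior medians, and 95% HPD coverage.
    """
    if n_test < 30:
        raise ValueError("n_test must be >= 30")
    priors = priors or default_priors()
    config = fixture.sample_config(scale=scale)
    scenarios = list(ScenarioId)
    master = np.random.SeedSequence(seed)
    s_table, s_train, s_test, s_obs, s_reg = (
        int(s) for s in master.generate_state(5, dtype=np.uint32)
    )
    n_val = max(1, int(round(val_fraction * n_train_per_scenario)))
    table = build_reference_table(
        scenarios, priors, n_train_per_scenario + n_val, config, seed=s_table
    )
    # per-scenario split keeps train and validation balanced
    train_idx, val_idx = [], []
    for scen in scenarios:
        idx = np.flatnonzero(table.labels == int(scen))
        train_idx.append(idx[:n_train_per_scenario])
        val_idx.append(idx[n_train_per_scenario:])
    train = table.subset(np.concatenate(train_idx))
    val = table.subset(np.concatenate(val_idx))
    model = train_classifier(train, val, hyper=hyper, seed=s_train)
    calib = calibrate_temperature(model, val)
    n_test_per_scenario = int(np.ceil(n_test / len(scenarios)))
    test = build_reference_table(scenarios, priors, n_test_per_scenario, config, seed=s_test)
    evaluation = evaluate_classifier(model, calib.temperature, test)
    p_chance = binomtest(
        int(round(evaluation.accuracy * len(test))), len(test), 1.0 / len(scenarios),
        alternative="greater",
    ).pvalue

    # ABC summaries for the reference come from the held-out simulations
    ref_probs = predict_probabilities(model, calib.temperature, test.images)

    regressor = train_regressor(
        train.restrict_to_scenario(pseudo_scenario), hyper=hyper, seed=s_reg
    )
    ref_for_params = test.restrict_to_scenario(pseudo_scenario)
    ref_preds = regressor.predict(ref_for_params.images)

    obs_seeds = np.random.SeedSequence(s_obs).generate_state(n_pseudo_observed, dtype=np.uint32)
    pp_rows, medians, truths, covered = [], [], [], {}
    tracked = regressor.param_names
    covered = {name: 0 for name in tracked}
    for s in obs_seeds:
        truth, gm = make_pseudo_observed(pseudo_scenario, fixture, scale, int(s), priors=priors)
        img = encode_image(gm, width=config.target_snps, row_order="within_column")
        obs_prob = predict_probabilities(model, calib.temperature, img.pixels[None])[0]
        sel = abc_select_model(obs_prob, ref_probs, test.labels, tolerance=abc_tolerance)
        pp_rows.append(sel.pp)
        obs_pred = regressor.predict(img.pixels[None])[0]
        post = abc_estimate_parameters(
            obs_pred, ref_preds, ref_for_params.params, tolerance=abc_tolerance,
            param_names=tracked,
        )
        medians.append(post.summary["median"].to_dict())
        truths.append(truth.as_dict())
        for name in tracked:
            low, high = post.summary.loc[name, ["hpd_low", "hpd_high"]]
            if low <= truths[-1][name] <= high:
                covered[name] += 1
    medians_df = pd.DataFrame(medians)
    truths_df = pd.DataFrame(truths)
    spearman = {
        name: float(spearmanr(truths_df[name], medians_df[name]).statistic) for name in tracked
    }
    coverage = {name: covered[name] / n_pseudo_observed for name in tracked}
    return {
        "accuracy": evaluation.accuracy,
        "confusion": evaluation.confusion,
        "p_value_vs_chance": float(p_chance),
        "temperature": calib.temperature,
        "calibration": calib,
        "pp_table": pd.DataFrame(pp_rows, columns=[s.name for s in scenarios]),
        "spearman": spearman,
        "coverage": coverage,
        "n_test": len(test),
    }
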