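import numpy as np
import pytest

from comboscreen import (ComboDesign, DoseResponseDataset, DrugTruth,
                         MedianEffectResults, gen_combination,
                         gen_dose_response)
from comboscreen.simulate import default_dose_ladder


@pytest.fixture
def drug_pair_truth():
    """Two drugs with unequal slopes and a 4:1 potency difference."""
    return DrugTruth("A", m_true=1.0, dm_true=2.0), DrugTruth("B", m_true=1.2,
                                                              dm_true=8.0)


@pytest.fixture
def exact_fit():
    def make(m, dm, series_id="x"):
        return MedianEffectResults(series_id, m=m, dm=dm, r_squared=1.0,
                                   n_points_used=5)
    return make


def make_combo_dataset(truth_a, truth_b, alpha, noise_sd=0.0, seed=0,
                       replicates=1, dilution_factors=(1, 2, 4, 8)):
    """Constant-CI combination series at the equipotent ratio."""
    rho1 = truth_a.dm_true / (truth_a.dm_true + truth_b.dm_true)
    design = ComboDesign(f"{truth_a.drug_id}+{truth_b.drug_id}", rho1, 1 - rho1,
                         (truth_a.dm_true, truth_b.dm_true),
                         tuple(dilution_factors))
    table = gen_combination(truth_a, truth_b, None, design, noise_sd=noise_sd,
                            seed=seed, replicates=replicates, alpha=alpha)
    ds = DoseResponseDataset.from_viability(
        design.pair_id, table["dose1_uM"] + table["dose2_uM"],
        table["viability"])
    return design, ds


def make_single_dataset(truth, noise_sd=0.0, seed=0, replicates=1, n_points=5):
    doses = default_dose_ladder(truth, n_points=n_points)
    table = gen_dose_response(truth, doses, replicates=replicates,
                              noise_sd=noise_sd, seed=seed)
    return DoseResponseDataset.from_viability(truth.drug_id, table["dose_uM"],
                                              table["viability"])
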