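"""Shared fixtures: registries, the H4 tail peptide, and small synthetic runs."""

from __future__ import annotations

import pytest

from diahist.chemistry import default_registry
from diahist.simulate import (
    FormTruth,
    SyntheticTruth,
    default_histone_truth,
    simulate_run,
    truth_table,
)
from diahist.targets import DigestPeptide, digest, enumerate_forms, group_isobaric, load_histones
from diahist.windows import fixed_scheme


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def h4_tail() -> DigestPeptide:
    """H4 4-17 GKGGKGLGKGGAKR, the canonical four-lysine acetylation peptide."""
    h4 = load_histones()["H4"]
    (pep,) = [p for p in digest(h4, "H4") if p.span == (4, 17)]
    assert pep.sequence == "GKGGKGLGKGGAKR"
    return pep


@pytest.fixture(scope="session")
def mono_ac_quartet(h4_tail):
    """The four H4 mono-acetyl positional isomers as one charge-2 group."""
    forms = enumerate_forms(h4_tail, {"K": ["ac"]}, max_mods=1)
    (group,) = group_isobaric(forms, charge=2, ppm_tol=10.0)
    return group


@pytest.fixture(scope="session")
def small_scheme():
    """A compact fixed scheme covering m/z 300-900 for fast simulations."""
    return fixed_scheme(312.5, 887.5, 27.0, 2.0, ms1_ms=100.0, ms2_ms=10.0,
                        overhead_ms=5.6)


@pytest.fixture
def small_truth_factory(small_scheme):
    """Builds compact truths (short gradient, few forms) for unit tests."""

    def build(form_truths, gradient_min=2.0, **kwargs) -> SyntheticTruth:
        return SyntheticTruth(
            forms=form_truths,
            scheme=small_scheme,
            gradient_min=gradient_min,
            **kwargs,
        )

    return build


@pytest.fixture(scope="session")
def default_noiseless():
    """Default truth, one noiseless run, its target table and quant output.

    Session-scoped because several tests only read from it.
    """
    from diahist.quant import quantify_run

    truth = default_histone_truth(seed=1)
    run = simulate_run(truth)
    table = truth_table(truth)
    quant = quantify_run(run, table)
    return truth, run, table, quant
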