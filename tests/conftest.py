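"""Shared fixtures: the reference bundle is fitted once per session."""

from __future__ import annotations

import numpy as np
import pytest

from psmcea import evaluate, fit_bundle, make_fixture
from psmcea.kmdata import as_ipd


@pytest.fixture(scope="session")
def bundle_total():
    return make_fixture("paper_like_total")


@pytest.fixture(scope="session")
def fitted_total(bundle_total):
    return fit_bundle(bundle_total)


@pytest.fixture(scope="session")
def results_total(fitted_total):
    return evaluate(fitted_total)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ipd(*records):
    """Shorthand: ipd((1, 1), (2, 0)) -> IPD frame."""
    return as_ipd(records)
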