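import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import noisesleep as ns

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return ns.default_registry()


@pytest.fixture(scope="session")
def pooled_ref():
    return ns.load_pooled_reference()


@pytest.fixture(scope="session")
def fits_ref(pooled_ref):
    return ns.fit_all_sources(pooled_ref, method="wnls")


@pytest.fixture(scope="session")
def rt_microdata():
    """Moderate synthetic road-traffic survey, scored and binned."""
    cfg = ns.SimConfig(n_respondents=4000, source="RT", seed=42)
    df, truth = ns.generate_survey(cfg)
    df = df.copy()
    df["hsd_score"] = ns.score_respondents(df)
    df["nl_center"] = ns.nl_bins(df["lnight_db"])
    return df, truth


def grid_search_fit(nl, p, w, a_range, b_range, rounds=8, grid=41):
    """Brute-force coarse-to-fine grid minimizer of the weighted SSE.

    Independent oracle for the curve fit: no derivatives, no optimizer.
    """
    nl = np.asarray(nl, float)
    p = np.asarray(p, float)
    w = np.asarray(w, float)
    (a_lo, a_hi), (b_lo, b_hi) = a_range, b_range
    best = None
    for _ in range(rounds):
        aa = np.linspace(a_lo, a_hi, grid)
        bb = np.linspace(b_lo, b_hi, grid)
        A, B = np.meshgrid(aa, bb, indexing="ij")
        pred = 1.0 / (1.0 + np.exp(A[..., None] - B[..., None] * nl))
        sse = np.sum(w * (p - pred) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (aa[i], bb[j])
        da, db = (a_hi - a_lo) / (grid - 1), (b_hi - b_lo) / (grid - 1)
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
    return best
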