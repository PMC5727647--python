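import numpy as np
import pandas as pd
import pytest

import methcoord as mc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def seven_gene_config():
    """One-tissue 7-gene study with strong equicorrelation (rho=0.6)."""
    return mc.SimulationConfig(
        tissues=("liver",),
        conditions=("normal",),
        samples_per_group=100,
        target_correlation={("liver", "normal"): mc.compound_symmetric(7, 0.6)},
        seed=7,
    )


@pytest.fixture
def tiny_expression():
    """4 genes x 6 samples, two tissues, deterministic values."""
    rng = np.random.default_rng(0)
    genes = ["DNMT1", "TET1", "TET2", "TDG"]
    samples = [f"s{i}" for i in range(6)]
    data = pd.DataFrame(rng.lognormal(0, 0.3, size=(4, 6)), index=genes, columns=samples)
    info = pd.DataFrame(
        {
            "tissue": ["liver"] * 3 + ["lung"] * 3,
            "condition": ["normal"] * 6,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return mc.ExpressionMatrix(data, info)


@pytest.fixture
def matched_panels():
    """Matched normal/tumor panels over 4 tissues with planted coordination loss."""
    cfg = mc.matched_study_config(
        ["liver", "lung", "kidney", "colon"],
        normal_rho=0.6, tumor_rho=0.0, samples_per_group=150, seed=11,
    )
    expr = mc.simulate_study(cfg)
    genes = list(cfg.panel_genes)
    normal = [mc.build_panel(expr, genes, tissue=t, condition="normal") for t in cfg.tissues]
    tumor = [mc.build_panel(expr, genes, tissue=t, condition="tumor") for t in cfg.tissues]
    return normal, tumor


def bh_stepup_oracle(p):
    """Independent brute-force Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


def pearson_oracle(x, y):
    """Definition-level Pearson coefficient: covariance over the sd product."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def paired_t_oracle(diffs):
    """Closed-form paired t and two-sided p from the difference vector."""
    from scipy import stats

    d = np.asarray(diffs, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 1))
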