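import numpy as np
import pandas as pd
import pytest

from targetmr.instruments import HarmonizedSet


def make_hset(beta_exp, se_exp, beta_out, se_out, n_exp=100_000, n_out=100_000,
              chrom="1", pos_start=1_000_000, pos_step=100_000):
    """Build a HarmonizedSet directly from arrays (test convenience)."""
    k = len(beta_exp)
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_exp = np.asarray(se_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    f = (beta_exp / se_exp) ** 2
    r2_exp = f / (f + n_exp - 2)
    f_out = (beta_out / se_out) ** 2
    r2_out = f_out / (f_out + n_out - 2)
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(k)],
            "chrom": chrom,
            "pos": pos_start + pos_step * np.arange(k),
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_exp": 0.3,
            "eaf_out": 0.3,
            "n_exp": float(n_exp),
            "n_out": float(n_out),
            "f_stat": f,
            "r2_exp": r2_exp,
            "r2_out": r2_out,
            "steiger_keep": r2_exp > r2_out,
            "pav_flag": False,
        }
    )
    return HarmonizedSet(df, "exposure", "outcome")


@pytest.fixture
def toy_hset():
    """Two equally-weighted SNPs with ratios 0.4 and 0.6."""
    return make_hset([1.0, 1.0], [0.01, 0.01], [0.4, 0.6], [0.1, 0.1])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_assoc(rows):
    """Association frame from (id, chrom, pos, ea, oa, eaf, beta, se, p, n)."""
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pval", "n"],
    )


def clump_random_case(seed, n=50):
    """Random multi-chromosome association set with blocky LD."""
    from targetmr.io import LDMatrix

    rng = np.random.default_rng(seed)
    ids = [f"v{i}" for i in range(n)]
    blocks = np.zeros((n, n))
    size = 5
    for s in range(0, n, size):
        e = min(s + size, n)
        sub = rng.uniform(-0.9, 0.9, size=(e - s, e - s))
        sub = (sub + sub.T) / 2
        np.fill_diagonal(sub, 1.0)
        blocks[s:e, s:e] = sub
    ld = LDMatrix(ids, np.clip(blocks, -1, 1))
    df = make_assoc([
        (
            ids[i], str(rng.integers(1, 3)),
            int(rng.integers(1, 30_000_000)), "A", "G", 0.3, 0.2, 0.01,
            float(rng.uniform(1e-20, 1e-8)), 1e5,
        )
        for i in range(n)
    ])
    return df, ld


def clump_oracle(df, ld, r2_thresh, window_bp):
    """Independent clumping route: sequential keep in p-order, plain loops."""
    order = df.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    )
    kept = []
    for row in order.itertuples(index=False):
        blocked = False
        for prev in kept:
            if prev.chrom != row.chrom:
                continue
            if abs(prev.pos - row.pos) > window_bp:
                continue
            r2 = ld.r2(prev.variant_id, row.variant_id)
            if r2 is not None and r2 >= r2_thresh:
                blocked = True
                break
        if not blocked:
            kept.append(row)
    return sorted(r.variant_id for r in kept)
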