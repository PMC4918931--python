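import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import divrao as dv
from divrao.data import ValidationError
from .conftest import brute_force_multisite_sorensen


def inc_from_sets(sets, universe=None):
    universe = universe or sorted(set().union(*sets))
    rows = [[1 if sp in s else 0 for sp in universe] for s in sets]
    return pd.DataFrame(rows, index=[f"site{i}" for i in range(len(sets))],
                        columns=universe)


def test_identical_sites_have_no_beta():
    dec = dv.multisite_sorensen_decompose(inc_from_sets([{"a", "b"}, {"a", "b"}]))
    assert dec.beta_total == dec.beta_turnover == dec.beta_nestedness == 0.0


def test_perfect_nesting():
    dec = dv.multisite_sorensen_decompose(inc_from_sets([{"a", "b", "c"}, {"a", "b"}]))
    assert dec.beta_turnover == pytest.approx(0.0, abs=1e-15)
    assert dec.beta_total == pytest.approx(0.2, abs=1e-15)
    assert dec.beta_nestedness == pytest.approx(0.2, abs=1e-15)


def test_complete_replacement():
    dec = dv.multisite_sorensen_decompose(inc_from_sets([{"a", "b"}, {"c", "d"}]))
    assert dec.beta_turnover == pytest.approx(1.0)
    assert dec.beta_total == pytest.approx(1.0)
    assert dec.beta_nestedness == pytest.approx(0.0, abs=1e-15)


def test_pairwise_case_reproduces_classic_sorensen():
    rng = np.random.default_rng(5)
    for _ in range(20):
        s1 = set(np.flatnonzero(rng.random(12) < 0.5))
        s2 = set(np.flatnonzero(rng.random(12) < 0.5))
        if not s1 or not s2:
            continue
        a = len(s1 & s2)
        b, c = len(s1 - s2), len(s2 - s1)
        if 2 * a + b + c == 0:
            continue
        dec = dv.multisite_sorensen_decompose(inc_from_sets([s1, s2], list(range(12))))
        assert dec.beta_total == pytest.approx((b + c) / (2 * a + b + c), abs=1e-12)


@settings(max_examples=80, deadline=None)
@given(
    st.lists(
        st.sets(st.integers(min_value=0, max_value=9), min_size=1, max_size=10),
        min_size=2,
        max_size=5,
    )
)
def test_additivity_and_bruteforce_agreement(sets):
    dec = dv.multisite_sorensen_decompose(inc_from_sets(sets, list(range(10))))
    assert dec.beta_turnover + dec.beta_nestedness == pytest.approx(
        dec.beta_total, abs=1e-12
    )
    turn, nest, total = brute_force_multisite_sorensen([set(s) for s in sets])
    assert dec.beta_turnover == pytest.approx(turn, abs=1e-12)
    assert dec.beta_total == pytest.approx(total, abs=1e-12)
    assert 0.0 <= dec.beta_turnover <= dec.beta_total <= 1.0


def test_site_order_does_not_change_decomposition():
    rng = np.random.default_rng(11)
    for _ in range(20):
        sets = [
            set(np.flatnonzero(rng.random(8) < 0.5)) or {0}
            for _ in range(4)
        ]
        base = dv.multisite_sorensen_decompose(inc_from_sets(sets, list(range(8))))
        perm = [sets[i] for i in rng.permutation(4)]
        shuf = dv.multisite_sorensen_decompose(inc_from_sets(perm, list(range(8))))
        assert shuf.beta_total == pytest.approx(base.beta_total, abs=1e-12)
        assert shuf.beta_turnover == pytest.approx(base.beta_turnover, abs=1e-12)


def test_agreement_with_vegan_multisite_decomposition(tmp_path):
    """Independent oracle: vegan's multiple-site Sorensen decomposition."""
    rng = np.random.default_rng(7)
    B = (rng.random((6, 12)) < 0.45).astype(int)
    B[B.sum(axis=1) == 0, 0] = 1
    inc = pd.DataFrame(B, index=[f"s{i}" for i in range(6)],
                       columns=[f"x{j}" for j in range(12)])
    csv = tmp_path / "inc.csv"
    inc.to_csv(csv, index=False)
    out = subprocess.run(
        ["Rscript", "-e",
         f'suppressMessages(library(vegan));'
         f'm <- as.matrix(read.csv("{csv}"));'
         f'cat(nestedbetasor(m), sep="\\n")'],
        capture_output=True, text=True, check=True,
    )
    turn_r, nest_r, total_r = [float(x) for x in out.stdout.split()]
    dec = dv.multisite_sorensen_decompose(inc)
    assert dec.beta_turnover == pytest.approx(turn_r, abs=1e-6)
    assert dec.beta_nestedness == pytest.approx(nest_r, abs=1e-6)
    assert dec.beta_total == pytest.approx(total_r, abs=1e-6)


def test_empty_site_errors():
    inc = pd.DataFrame([[1, 1], [0, 0]], index=["s0", "s1"], columns=["a", "b"])
    with pytest.raises(ValidationError, match="zero entities"):
        dv.multisite_sorensen_decompose(inc)


class TestFunctionalUnits:
    def traits(self):
        return dv.TraitTable(
            pd.DataFrame(
                {
                    "guild": ["tunneler", "tunneler", "roller", "dweller"],
                    "biomass_g": [0.05, 0.06, 0.5, 0.9],
                },
                index=["a", "b", "c", "d"],
            )
        )

    def test_same_guild_same_class_collapse_to_one_unit(self):
        m = dv.CommunityMatrix(
            pd.DataFrame([[3, 2, 0, 0], [1, 0, 1, 0]], index=["t1", "t2"],
                         columns=["a", "b", "c", "d"])
        )
        inc = dv.functional_units(self.traits(), m)
        assert inc.loc["t1"].sum() == 1  # both tunnelers share one small class
        assert inc.shape[1] <= 6  # 3 guilds x 2 biomass classes at most

    def test_fully_redundant_pool_has_zero_fd_beta(self):
        traits = dv.TraitTable(
            pd.DataFrame(
                {"guild": ["tunneler"] * 4, "biomass_g": [0.1] * 4},
                index=["a", "b", "c", "d"],
            )
        )
        m = dv.CommunityMatrix(
            pd.DataFrame([[5, 1, 0, 0], [0, 0, 4, 2]], index=["t1", "t2"],
                         columns=["a", "b", "c", "d"])
        )
        h = dv.SpatialHierarchy({"t1": "G1", "t2": "G2"})
        fd = dv.decompose_beta2(m, h, traits, biomass_bins=1)
        td = dv.decompose_beta2(m, h)
        assert fd.beta_total == 0.0
        assert td.beta_total > 0.0


def test_beta1_per_group_and_beta2_shapes(default_run):
    m, t, h, _ = default_run
    per_group = dv.decompose_beta1(m, h)
    assert set(per_group) == set(h.groups)
    for dec in per_group.values():
        assert dec.n_sites == 3
    b2 = dv.decompose_beta2(m, h, t)
    assert b2.n_sites == 7 and b2.meta["facet"] == "FD"
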