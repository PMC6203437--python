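import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20180)


@pytest.fixture
def two_group_table(rng):
    """Small two-group phenotype table: one normal trait, one skewed, one with NaN."""
    n = 20
    ctrl = pd.DataFrame(
        {
            "animal_id": [f"CTRL_{i:03d}" for i in range(n)],
            "group": "CTRL",
            "normal_trait": rng.normal(10.0, 2.0, n),
            "skewed_trait": np.exp(rng.normal(0.0, 1.2, n)),
            "gappy_trait": rng.normal(5.0, 1.0, n),
        }
    )
    enr = pd.DataFrame(
        {
            "animal_id": [f"ENR_{i:03d}" for i in range(n)],
            "group": "ENR",
            "normal_trait": rng.normal(11.0, 2.0, n),
            "skewed_trait": np.exp(rng.normal(0.2, 1.2, n)),
            "gappy_trait": rng.normal(5.0, 1.5, n),
        }
    )
    table = pd.concat([ctrl, enr], ignore_index=True)
    table.loc[[2, 5, 25], "gappy_trait"] = np.nan
    return table


# Reference oracle values computed once with R 4.3.3 on the literal samples
# below (shapiro.test, t.test, var.test, wilcox.test with correct=TRUE,
# car::leveneTest center=median, cor.test method="spearman") and frozen here.
R_ORACLE_X = [10.081, 9.353, 9.368, 9.462, 9.722, 6.473, 9.784, 10.427,
              4.195, 11.93, 9.547, 11.203]
R_ORACLE_Y = [11.423, 6.459, 12.258, 14.433, 2.633, 10.103, 12.731, 8.828,
              11.367, 9.803, 5.357, 8.136, 13.624, 11.287]
R_ORACLE_SKEW = [1.1769, 0.8276, 1.8775, 0.9371, 1.8129, 0.6717, 1.3935,
                 0.3933, 0.5161, 1.6452, 0.9556, 0.6062, 0.7169, 0.4125,
                 0.5146, 1.2967, 0.789, 0.7788, 0.5855, 1.472]
R_ORACLE = {
    "shapiro_x": (0.820294318831, 0.0160875123018),
    "shapiro_skew": (0.911502176092, 0.0680816804337),
    "welch": (-0.553971177796, 22.0528489798, 0.585172688709),
    "var_test": (0.385593749554, 0.121883045533),
    "wilcox_ties": (12.5, 0.0795647345932),
    "brown_forsythe": (2.98238040196, 0.0970263724571),
    "spearman_ties": (0.0948016665352, 0.794475111367),
}
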