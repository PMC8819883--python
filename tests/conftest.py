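import numpy as np
import pandas as pd
import pytest

from fetometab.model import FeatureTable


def make_table(
    values: np.ndarray,
    n_qc: int = 0,
    organs: tuple[str, ...] = ("brain",),
    mode: str = "RP+",
    groups: tuple[str, str] = ("GF", "SPF"),
) -> FeatureTable:
    """Small hand-rolled FeatureTable: biological injections split evenly
    between the two groups across the given organs, plus trailing QCs."""
    n_feat, n_inj = values.shape
    n_bio = n_inj - n_qc
    assert n_bio % (2 * len(organs)) == 0, "biological injections must split evenly"
    per_cell = n_bio // (2 * len(organs))
    inj_rows = []
    i = 0
    for organ in organs:
        for group in groups:
            for k in range(per_cell):
                inj_rows.append(
                    {
                        "injection_id": f"{group}_{organ}_{k + 1}",
                        "sample_type": "biological",
                        "group": group,
                        "organ": organ,
                        "dam_id": f"{group}_dam{k % 3 + 1}",
                        "fetus_sex": "M" if k % 2 == 0 else "F",
                    }
                )
                i += 1
    for k in range(n_qc):
        inj_rows.append(
            {
                "injection_id": f"QC_{k + 1}",
                "sample_type": "qc",
                "group": "",
                "organ": "",
                "dam_id": "",
                "fetus_sex": "",
            }
        )
    inj = pd.DataFrame(inj_rows).set_index("injection_id")
    inj["injection_order"] = np.arange(1, n_inj + 1)
    feats = pd.DataFrame(
        {
            "mode": mode,
            "mz": np.linspace(100.0, 900.0, n_feat),
            "rt": np.linspace(1.0, 10.0, n_feat),
        },
        index=pd.Index([f"F{i + 1}" for i in range(n_feat)], name="feature_id"),
    )
    intensities = pd.DataFrame(
        np.array(values, dtype=float, copy=True), index=feats.index, columns=inj.index
    )
    return FeatureTable(intensities, feats, inj)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
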