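import numpy as np
import pandas as pd
import pytest

from chemscreen.fixtures import ExpressionPlan, FixturePlan, NetworkPlan


@pytest.fixture(scope="session")
def plan() -> FixturePlan:
    """Default study-scale fixture plan (16 actives / 82 unknowns, etc.)."""
    return FixturePlan(seed=1)


@pytest.fixture(scope="session")
def small_plan() -> FixturePlan:
    """Reduced plan for fast unit tests."""
    return FixturePlan(
        seed=3,
        n_actives=8,
        n_unknowns=20,
        n_out_of_box=5,
        n_planted_near_curve=7,
        n_similar=4,
        expression=ExpressionPlan(n_genes=120, n_tissues=6, samples_per_tissue=8,
                                  n_specific=10, n_low_expression=10),
        network=NetworkPlan(n_targets=30, n_disease=20, n_tissue=40,
                            overlap_disease=3, overlap_tissue=5, overlap_both=1),
    )


@pytest.fixture()
def smi_file(tmp_path):
    """Factory writing a .smi file + labels CSV; returns (smi, labels) paths."""

    def _write(entries, roles=None):
        smi = tmp_path / "in.smi"
        smi.write_text("".join(f"{s} {i}\n" for i, s in entries))
        ids = [i for i, _ in entries]
        labels = tmp_path / "labels.csv"
        pd.DataFrame(
            {"id": ids, "role": roles or ["unknown"] * len(ids)}
        ).to_csv(labels, index=False)
        return smi, labels

    return _write


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
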