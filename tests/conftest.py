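import numpy as np
import pytest

from apmstools.core import Condition, ProteinQuantTable, SampleInfo, StudyDesign


def make_table(values, missing=None, scale_tag="log2", sample_ids=None, protein_ids=None):
    """Small-table factory used throughout the suite."""
    values = np.asarray(values, dtype=float)
    missing = (
        np.zeros_like(values, dtype=bool) if missing is None else np.asarray(missing, bool)
    )
    n_p, n_s = values.shape
    return ProteinQuantTable(
        protein_ids=protein_ids or [f"P{i}" for i in range(n_p)],
        intensities=values,
        sample_ids=sample_ids or [f"S{j}" for j in range(n_s)],
        missing_mask=missing,
        scale_tag=scale_tag,
    )


def make_two_group_design(n_a, n_b, cond_a=Condition.BAIT_INTACT, cond_b=Condition.GST_CTRL,
                          sample_ids=None):
    """Design whose first n_b samples are cond_b (control) and the rest cond_a."""
    ids = sample_ids or [f"S{j}" for j in range(n_a + n_b)]
    samples = [SampleInfo(ids[j], cond_b, j + 1) for j in range(n_b)] + [
        SampleInfo(ids[n_b + j], cond_a, j + 1) for j in range(n_a)
    ]
    return StudyDesign(samples)


def make_paired_design(n_pairs, sample_ids=None):
    ids = sample_ids or [
        s for k in range(n_pairs) for s in (f"GTPGS_{k + 1}", f"GDPBS_{k + 1}")
    ]
    samples = []
    for k in range(n_pairs):
        samples.append(SampleInfo(ids[2 * k], Condition.BAIT_GTPGS, k + 1, pair_id=f"L{k + 1}"))
        samples.append(SampleInfo(ids[2 * k + 1], Condition.BAIT_GDPBS, k + 1, pair_id=f"L{k + 1}"))
    return StudyDesign(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
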