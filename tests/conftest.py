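import numpy as np
import pytest

from pccd.datamodel import CellClass, CellRecord, OrderedSequence, Specimen, SpecimenSet
from pccd.synthetic import GeneratorConfig, TFSpec, generate_cohort


def make_sequence(calls, tf="TF1", specimen_id="S1", distances=None):
    """Ordered sequence straight from a call list (descending dummy distances)."""
    calls = [bool(c) for c in calls]
    if distances is None:
        distances = list(np.linspace(100, 10, num=len(calls)))
    return OrderedSequence(
        specimen_id=specimen_id, tf=tf, calls=calls, distances=list(distances)
    )


def make_sequences(call_lists, tf="TF1"):
    return [
        make_sequence(c, tf=tf, specimen_id=f"S{i}") for i, c in enumerate(call_lists)
    ]


@pytest.fixture
def tiny_specimen():
    """NB at (5,5,5) plus three motoneurons at known distances."""
    cells = [
        CellRecord("nb", CellClass.NB, 5.0, 5.0, 5.0),
        CellRecord("c1", CellClass.MN, 8.0, 9.0, 5.0, {"TF1": False}),   # d=5
        CellRecord("c2", CellClass.MN, 5.0, 5.0, 25.0, {"TF1": True}),   # d=20
        CellRecord("c3", CellClass.MN, 35.0, 5.0, 5.0, {"TF1": True}),   # d=30
    ]
    return Specimen(
        specimen_id="S1", cells=cells, reference_cell_id="nb", stained_tfs={"TF1"}
    )


def zero_noise_config(tf_specs=None, n_mn=39, seed=0, **kw):
    """Generator settings with every stochastic ingredient switched off."""
    if tf_specs is None:
        tf_specs = {
            "one": TFSpec(intervals=[(16, 23)], p_in=1.0, p_out=0.0, boundary_jitter=0),
            "two": TFSpec(
                intervals=[(5, 11), (27, 33)], p_in=1.0, p_out=0.0, boundary_jitter=0
            ),
        }
    return GeneratorConfig(
        n_mn=n_mn,
        count_sd=0.0,
        pos_noise_sd=0.0,
        tf_specs=tf_specs,
        seed=seed,
        **kw,
    )


@pytest.fixture
def zero_noise_cohort():
    cfg = zero_noise_config()
    return generate_cohort(cfg, 20)
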