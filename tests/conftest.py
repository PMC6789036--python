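import numpy as np
import pytest

from wyldomkit.msa_core import Alignment, SequenceRecord, progressive_align
from wyldomkit.phmm_engine import build_profile, calibrate
from wyldomkit.synthetic_data import (
    default_library,
    emit_collection,
    seed_instances,
    survey_config,
)


@pytest.fixture(scope="session")
def toy_alignment():
    return Alignment([
        ("x1", "ACDEFGHIKL"),
        ("x2", "ACDEFGHIKL"),
        ("x3", "ACDEYGHIKL"),
    ])


@pytest.fixture(scope="session")
def toy_model(toy_alignment):
    model = build_profile(toy_alignment, name="toy")
    calibrate(model, n_random=150, length=80, seed=1)
    return model


@pytest.fixture(scope="session")
def library():
    return default_library()


def build_reference_models(lib, n_seed=30, sub_rate=0.15, indel_rate=0.02,
                           base_seed=100, calib_seed=7):
    """Build and calibrate one profile per archetype from noisy seed instances."""
    models = []
    for i, (name, arch) in enumerate(lib.items()):
        insts = seed_instances(arch, n_seed, sub_rate, indel_rate,
                               seed=base_seed + i)
        aln = progressive_align(insts)
        m = build_profile(aln, name=name, clan=arch.clan)
        calibrate(m, n_random=150, length=300, seed=calib_seed)
        models.append(m)
    return models


@pytest.fixture(scope="session")
def reference_models(library):
    return build_reference_models(library)


@pytest.fixture(scope="session")
def survey_collection(library):
    """The packaged survey-scale collection: ~600 planted proteins."""
    return emit_collection(survey_config(seed=11), library)


@pytest.fixture(scope="session")
def survey_annotations(reference_models, survey_collection):
    from wyldomkit.architecture_classifier import annotate_proteome, resolve_overlaps

    ann = annotate_proteome(reference_models, survey_collection.records)
    return {sid: resolve_overlaps(h) for sid, h in ann.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_protein(rng, length):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, 20, length))
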