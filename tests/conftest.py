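import numpy as np
import pytest

from flyatlas.synthetic import SyntheticSpec, generate_atlas, generate_embryo_set


@pytest.fixture(scope="session")
def paired_spec():
    """Two 'species' with identical geometry; the second's expression domains
    are shifted posteriorly by 2% egg length."""
    return SyntheticSpec(
        seed=11, n_species=2, species_names=("refsp", "tgtsp"),
        egg_length=(400.0, 400.0), max_radius=(80.0, 80.0),
        n_nuclei=(1500, 1500), shift_field=(0.0, 0.02),
        temporal_offset=(0, 0),
    )


@pytest.fixture(scope="session")
def atlas_pair(paired_spec):
    ref, _ = generate_atlas(paired_spec, 0)
    tgt, truth = generate_atlas(paired_spec, 1)
    return ref, tgt, truth


@pytest.fixture(scope="session")
def small_atlas():
    """One small species atlas (600 nuclei) for IO/cell-type tests."""
    spec = SyntheticSpec(
        seed=7, n_species=1, species_names=("solo",),
        egg_length=(400.0,), max_radius=(80.0,), n_nuclei=(600,),
        shift_field=(0.0,), temporal_offset=(0,),
    )
    atlas, truth = generate_atlas(spec, 0)
    return spec, atlas, truth


@pytest.fixture(scope="session")
def uniform_atlas():
    """Furrow-free embryo with uniform nuclear packing (2000 nuclei)."""
    spec = SyntheticSpec(
        seed=13, n_species=1, species_names=("unif",),
        egg_length=(400.0,), max_radius=(80.0,), n_nuclei=(2000,),
        shift_field=(0.0,), temporal_offset=(0,), furrow_depressions=(),
    )
    atlas, _ = generate_atlas(spec, 0)
    return spec, atlas


@pytest.fixture(scope="session")
def embryo_set(paired_spec, atlas_pair):
    """Eight embryos of the reference species at the final cohort,
    with the default 1%-of-max per-nucleus noise."""
    ref = atlas_pair[0]
    embryos, truth = generate_embryo_set(paired_spec, 8, cohort=6, atlas=ref)
    return embryos, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
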