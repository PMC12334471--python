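import numpy as np
import pandas as pd
import pytest

from fishdelt.model import ModelData, ModelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def tiny_observations():
    """Nine fish over two streams, two species, two agencies."""
    return pd.DataFrame(
        {
            "stream_id": ["c1", "c1", "c1", "c2", "c2", "c2", "c2", "c1", "c2"],
            "species": ["A", "A", "B", "A", "B", "B", "A", "B", "A"],
            "agency": ["ag1", "ag1", "ag1", "ag2", "ag2", "ag2", "ag2", "ag1", "ag2"],
            "ecoregion": ["e1", "e1", "e1", "e2", "e2", "e2", "e2", "e1", "e2"],
            "year": [2008, 2010, 2015, 2019, 2012, 2013, 2011, 2016, 2018],
            "delt": [0, 1, 0, 0, 1, 0, 0, 0, 1],
        }
    )


def random_model_case(rng, variant="conditional", n=40, n_streams=8, P=3,
                      beta_prior="horseshoe"):
    """A small random (spec, data, point) triple for density tests."""
    from fishdelt.model import ParameterPoint

    agencies = ("ag1", "ag2")
    ecoregions = ("e1", "e2", "e3")
    species = ("s1", "s2") if variant != "species_specific" else ()
    predictors = tuple(f"p{j}" for j in range(P)) if variant != "unconditional" else ()
    spec = ModelSpec(
        variant=variant,
        agencies=agencies,
        ecoregions=ecoregions,
        species=species,
        predictors=predictors,
        beta_prior=beta_prior,
    )
    data = ModelData(
        y=rng.integers(0, 2, n),
        stream_idx=rng.integers(0, n_streams, n),
        X_stream=rng.standard_normal((n_streams, len(predictors))),
        agency_idx=rng.integers(0, len(agencies), n),
        region_idx=rng.integers(0, len(ecoregions), n),
        species_idx=rng.integers(0, 2, n) if species else None,
    )
    kwargs = dict(
        beta0=float(rng.normal()),
        gamma=rng.normal(size=len(agencies)),
        phi=rng.normal(size=len(ecoregions)),
        sigma_agency=float(rng.uniform(0.2, 2.0)),
        sigma_region=float(rng.uniform(0.2, 2.0)),
    )
    if species:
        kwargs["eta"] = rng.normal(size=len(species))
        kwargs["sigma_species"] = float(rng.uniform(0.2, 2.0))
    if predictors:
        kwargs["beta"] = rng.normal(size=len(predictors))
        if beta_prior == "horseshoe":
            kwargs["tau"] = float(rng.uniform(0.05, 1.0))
            kwargs["lam"] = rng.uniform(0.2, 3.0, size=len(predictors))
            kwargs["c"] = float(rng.uniform(0.5, 4.0))
    point = ParameterPoint(**kwargs)
    return spec, data, point
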