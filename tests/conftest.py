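import numpy as np
import pytest

from subspec.hmm import WeightConstants, build_subfamily_profile, score_sequence
from subspec.synthetic import (
    PlantedMsaSpec,
    default_schemes,
    generate_subfamily_msas,
)

#: One fixed planted-alignment study shared across the suite (the toy-scale
#: separation conditions: 5 subfamilies x 20 sequences x 200 columns).
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def msa_result():
    return generate_subfamily_msas(PlantedMsaSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def profile_builds(msa_result):
    schemes = default_schemes(msa_result.spec.subfamilies)
    return {
        sf: build_subfamily_profile(
            msa_result.subfamily_alignments, schemes[sf], WeightConstants(), name=sf
        )
        for sf in msa_result.spec.subfamilies
    }


@pytest.fixture(scope="session")
def holdout_scores(msa_result, profile_builds):
    """Score matrix: (subfamily of origin, sequence id) -> profile -> bits,
    for both the weighted and the unweighted (all-weights-one) profiles."""
    from subspec.hmm import WeightedProfile

    weighted = {sf: b.profile for sf, b in profile_builds.items()}
    unweighted = {
        sf: WeightedProfile(sf, p.baseline, np.ones(p.n_columns), p.column_map)
        for sf, p in weighted.items()
    }
    out = {"weighted": {}, "unweighted": {}}
    for origin, seqs in msa_result.holdout_sequences.items():
        for sid, seq in seqs.items():
            for kind, profiles in (("weighted", weighted), ("unweighted", unweighted)):
                out[kind][(origin, sid)] = {
                    name: score_sequence(p, seq) for name, p in profiles.items()
                }
    return out
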