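"""Build a position-weighted subfamily profile and classify held-out sequences.

Generates a planted five-subfamily alignment study, builds the weighted
profile of the target subfamily, and scores held-out sequences from the
target and its closest neighbour against it.
"""

import collections

from subspec.hmm import WeightConstants, build_subfamily_profile, score_sequence
from subspec.synthetic import PlantedMsaSpec, default_schemes, generate_subfamily_msas

msa = generate_subfamily_msas(PlantedMsaSpec(seed=1))
target = msa.spec.subfamilies[0]
schemes = default_schemes(msa.spec.subfamilies)
build = build_subfamily_profile(msa.subfamily_alignments, schemes[target],
                                WeightConstants(), name=target)

print(f"profile for {target}: {build.profile.n_columns} columns")
print("position types:", dict(collections.Counter(build.typing.ptype)))
print("weight range: %.3f .. %.3f" % (build.weights.min(), build.weights.max()))

own = next(iter(msa.holdout_sequences[target].values()))
closest = next(iter(msa.holdout_sequences[schemes[target].closest[0]].values()))
print("held-out %s sequence scores %+.1f bits (positive: claimed by the profile)"
      % (target, score_sequence(build.profile, own)))
print("held-out %s sequence scores %+.1f bits (negative: rejected)"
      % (schemes[target].closest[0], score_sequence(build.profile, closest)))
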