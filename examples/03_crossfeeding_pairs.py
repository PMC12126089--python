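"""Label bacterial pairs by simulation and train the cross-feeding classifier.

Every unordered pair of a 12-member pool is simulated as a two-member
community; a pair is a cross-feeding pair when some medium metabolite is
actually transferred between the members at the optimum.  A gradient-boosted
classifier then learns to predict that label from the two organisms'
reaction presence/absence vectors alone.
"""

import numpy as np

from butyrnet import (
    UniverseSpec,
    build_pair_records,
    build_universe,
    make_medium,
    make_universe,
    presence_vector,
    sample_pool,
    train_interaction_classifier,
)

universe = make_universe(UniverseSpec(seed=2))
medium = make_medium(universe, richness=1.0, seed=2)
pool, manifest = sample_pool(universe, n_organisms=12, n_producers=4, seed=2,
                             medium=medium)
universe_ids = build_universe(pool)

records = build_pair_records(pool, medium, universe_ids)
positives = sum(r.label for r in records)
print(f"{len(records)} pairs labelled; {positives} cross-feeding")

classifier = train_interaction_classifier(records, universe_ids, seed=2)
pv = {n.organism_id: presence_vector(n, universe_ids) for n in pool}
probs = np.array([classifier.pair_probability(pv, *r.pair) for r in records])
labels = np.array([r.label for r in records])
print(f"mean predicted probability | cross-feeding pairs    : "
      f"{probs[labels == 1].mean():.3f}")
print(f"mean predicted probability | non-interacting pairs  : "
      f"{probs[labels == 0].mean():.3f}")
a, b = records[0].pair
print(f"prob({a},{b}) = prob({b},{a}) = {classifier.pair_probability(pv, a, b):.3f}"
      " (symmetric by canonical pair ordering)")
# These probabilities fill the tail of every consortium feature vector.
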