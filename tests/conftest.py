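"""Shared fixtures.

The expensive fixture is the end-to-end synthetic study: a 40-image corpus
spanning 800-3000 cells/mm^2 with 10% fully ungradable images, a U-Net
trained at reduced scale on 30 gradable images, and predictions on the 10
held-out images.  It is session-scoped so the end-to-end tests share one
training run.
"""

import sys
from dataclasses import dataclass
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cecseg.estimators import UNetBorderSegmenter
from cecseg.synthetic import generate_corpus

# reduced-scale study conditions for the end-to-end run
CORPUS_SEED = 7
N_CORPUS = 40
DENSITY_RANGE = (800.0, 3000.0)
UNGRADABLE_FRACTION = 0.1
N_TRAIN = 30
TRAIN_KW = dict(
    root_features=8, epochs=12, iterations_per_epoch=100, batch_size=8, random_state=0
)


@dataclass
class EndToEndStudy:
    manifest: object
    samples: list
    train_samples: list
    heldout_gradable: list
    heldout_ungradable: list
    segmenter: UNetBorderSegmenter
    results_gradable: list
    results_ungradable: list
    densities_gradable: list
    densities_ungradable: list


def build_end_to_end_study(corpus_dir: str) -> EndToEndStudy:
    manifest, samples = generate_corpus(
        N_CORPUS,
        corpus_dir,
        seed=CORPUS_SEED,
        density_range=DENSITY_RANGE,
        ungradable_fraction=UNGRADABLE_FRACTION,
    )
    gradable = [s for s, r in zip(samples, manifest.records) if not r.ungradable]
    ungradable = [s for s, r in zip(samples, manifest.records) if r.ungradable]
    train_samples = gradable[:N_TRAIN]
    heldout_gradable = gradable[N_TRAIN:]

    seg = UNetBorderSegmenter(**TRAIN_KW)
    seg.fit([s.image for s in train_samples], [s.truth_centroids for s in train_samples])

    results_g = seg.predict([s.image for s in heldout_gradable])
    results_u = seg.predict([s.image for s in ungradable])
    dens_g = seg.predict_density([s.image for s in heldout_gradable])
    dens_u = seg.predict_density([s.image for s in ungradable])
    return EndToEndStudy(
        manifest=manifest,
        samples=samples,
        train_samples=train_samples,
        heldout_gradable=heldout_gradable,
        heldout_ungradable=ungradable,
        segmenter=seg,
        results_gradable=results_g,
        results_ungradable=results_u,
        densities_gradable=dens_g,
        densities_ungradable=dens_u,
    )


@pytest.fixture(scope="session")
def end_to_end_study(tmp_path_factory) -> EndToEndStudy:
    return build_end_to_end_study(str(tmp_path_factory.mktemp("corpus")))
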