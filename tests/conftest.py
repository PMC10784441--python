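"""Shared fixtures: the session-trained pretext encoder and patch corpus.

The encoder is trained once per session on a 500-patch synthetic corpus
(50 phantom patients x 10 patches, patient-disjoint 7:1:2 split) and reused
by every test that needs deep features — the pretext task never sees outcome
labels, so sharing one encoder across cohorts leaks nothing.
"""

import numpy as np
import pytest

from ptrarad import deepfeat, phantom


@pytest.fixture(scope="session")
def pretext_corpus():
    patches, labels, pids = phantom.sample_patches(50, 10, seed=123)
    tr, va, te = phantom.grouped_split(pids, seed=123)
    return {
        "patches": patches,
        "labels": labels,
        "patient_ids": pids,
        "train": tr,
        "val": va,
        "test": te,
    }


@pytest.fixture(scope="session")
def pretext_run(pretext_corpus):
    c = pretext_corpus
    encoder = deepfeat.build_encoder(seed=123)
    schedule = deepfeat.TrainingSchedule(max_epochs=12, seed=123)
    trained = deepfeat.train_pretext(
        encoder,
        c["patches"][c["train"]],
        c["labels"][c["train"]],
        c["patches"][c["val"]],
        c["labels"][c["val"]],
        schedule,
    )
    test_acc = float(
        (encoder.predict_proba(c["patches"][c["test"]]).argmax(axis=1) == c["labels"][c["test"]]).mean()
    )
    return {"trained": trained, "encoder": encoder, "test_accuracy": test_acc, "n_patches": len(c["patches"])}
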