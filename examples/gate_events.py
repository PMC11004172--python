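"""Train EverFlow on a pooled labeled-event set and gate a new patient.

Mirrors the per-event cell-typing phase: identical cell types from many
patients are amalgamated into one balanced training pool, the 1-D CNN is
trained with the Ranger optimizer, and a fresh simulated patient is gated.
The per-class recall shows which populations are recovered; the composition
of the AI gating is what the patient-level classifier consumes.
"""

import numpy as np

from leukoflow import default_phenotypes, default_templates, simulate_patient
from leukoflow.alot_synth import sample_training_pool
from leukoflow.everflow_model import (
    EverFlowConfig,
    classify_events,
    per_class_recall,
    train_event_classifier,
)
from leukoflow.features import transform_events

pool_em, pool_labels = sample_training_pool(default_templates(), 1000, seed=0)
config = EverFlowConfig(seed=0, max_epochs=12)
model = train_event_classifier(transform_events(pool_em), pool_labels, config)
print(f"trained {len(model.history.train_loss)} epochs, "
      f"final val accuracy {model.history.val_accuracy[-1]:.3f}")

patient = simulate_patient(default_phenotypes()["B-ALL"], 5000, seed=7)
pred, proba = classify_events(model, patient.em)
recall = per_class_recall(patient.labels, pred)
print(f"\nB-ALL patient, {patient.em.n_events} events; per-class recall:")
for name, r in recall.items():
    if r is not None:
        print(f"  {name:<14} {r:5.3f}")
print(f"overall per-event agreement: {(pred == patient.labels).mean():.3f}")
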