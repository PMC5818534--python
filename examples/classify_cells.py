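"""Cell-class prediction from electrophysiological features.

Builds a small bank of regular- and fast-spiking ground-truth cells,
measures their training features from one suprathreshold step each, and
asks a linear maximum-margin classifier (with recursive feature
elimination and five-fold cross-validation) to predict the class labels.
"""

import numpy as np

from neurofit import StimulusProtocol, simulate, sweep_features
from neurofit.cell_classes import ClassifierDataset, train_and_score
from neurofit.ephys_features import FEATURE_NAMES
from neurofit.synthetic_data import find_rheobase, make_cell_bank

bank = make_cell_bank(6, seed=7)
rows, labels = [], []
for cell in bank:
    model = cell.build()
    rheo = find_rheobase(model, solver=cell.solver)
    proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                             amplitude=rheo + 40.0, total_duration=1.35)
    f = sweep_features(simulate(model, proto, cell.solver))
    rows.append([f[n] if f[n] is not None else 0.0 for n in FEATURE_NAMES])
    labels.append(cell.class_label)

ds = ClassifierDataset(np.array(rows), FEATURE_NAMES, np.array(labels),
                       "model_features")
res = train_and_score(ds, folds=5, seed=0)
print(f"cells: {len(bank)} ({labels.count('regular_spiking')} regular-, "
      f"{labels.count('fast_spiking')} fast-spiking)")
print(f"cross-validated accuracy: {res.overall_accuracy:.2f}")
print("row-normalized confusion matrix (rows = true class):")
for cls, row in zip(res.classes, res.confusion):
    print(f"  {cls:>16s}: " + "  ".join(f"{x:.2f}" for x in row))
print(f"predictors kept by RFE: {', '.join(res.selected_predictors)}")
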