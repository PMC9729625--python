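"""Match Between Runs: train the evidence-matching model on synthetic
replicate runs, then transfer quantitation into missing cells of a fresh
run pair under FQR control.

The printed numbers show how many missing (glycopeptide, run) cells were
filled, the score and intensity of one accepted transfer next to the
generator's ground truth, and the median relative error of all accepted
transfers."""

import warnings

import numpy as np

from glyquant.matchnet import mine_training_pairs, train
from glyquant.mbr import match_between_runs
from glyquant.synthio import make_replicates

warnings.filterwarnings("ignore")

runs, ids, _ = make_replicates(130, n_runs=6, seed=77)
pairs = mine_training_pairs(runs, ids, n_pos=500, n_neg=500, seed=77)
log: list[dict] = []
model = train(pairs, epochs=25, seed=77, log=log)
n_pos = sum(p.label == 1 for p in pairs)
print(
    f"mined {n_pos} positive / {len(pairs) - n_pos} negative pairs; "
    f"final training loss {log[-1]['loss']:.3f}"
)

runs2, ids2, truth2 = make_replicates(60, n_runs=2, seed=303)
results, matrix = match_between_runs(runs2, ids2, model, seed=1)
attempts = [r for r in results if not r.is_decoy]
accepted = [r for r in attempts if r.accepted]
print(f"transfer attempts: {len(attempts)}   accepted at FQR<=0.01: {len(accepted)}")

errors = []
shown = False
for r in accepted:
    peptide, _, _, charge = (
        r.glycopeptide_key[0],
        r.glycopeptide_key[1],
        r.glycopeptide_key[2],
        r.glycopeptide_key[3],
    )
    row = truth2[(truth2.peptide == peptide) & (truth2.run_id == r.target_run)]
    if len(row) != 1:
        continue
    true_area = float(row.true_area.iloc[0])
    errors.append(abs(r.intensity / true_area - 1.0))
    if not shown:
        print("example accepted transfer:")
        print(
            f"  peptide {peptide}/{charge}+  score {r.score:.3f}  "
            f"intensity {r.intensity:.1f}  (true area {true_area:.1f})"
        )
        shown = True
print(
    "median |recovered/true - 1| over accepted transfers: "
    f"{100 * np.median(errors):.1f}%"
)
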