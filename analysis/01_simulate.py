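"""Generate the synthetic study dataset and record what was planted.

Emulates the sequencing design of the VPA study: 14 glioma cell lines
(7 adherent, 7 stem-like) profiled before and after valproic acid, with
a designated 30-gene "transporter" family of which 12 members are
up-regulated by treatment and carry concordant promoter ChIP regions.
"""

import json

from common import DATASET, RESULTS, SEED, dataset_dir
from vpaglio.simulate import TruthManifest

dataset_dir()
truth = TruthManifest.from_json(DATASET / "truth.json")

summary = {
    "seed": SEED,
    "n_genes": truth.params["n_genes"],
    "n_planted_up": len(truth.planted_up),
    "family_size": len(truth.family),
    "n_family_planted": len(truth.family_planted),
    "n_euchromatin_concordant": len(truth.euchromatin_concordant),
    "n_subtype_signature_genes": len(truth.mes_genes),
    "dose_response_curves": len(truth.dose_truth),
}
RESULTS.mkdir(exist_ok=True)
with open(RESULTS / "01_dataset_summary.json", "w") as fh:
    json.dump(summary, fh, indent=1)

print("dataset:", DATASET)
for k, v in summary.items():
    print(f"  {k}: {v}")
print(
    f"planted {summary['n_planted_up']} up-regulated genes, "
    f"{summary['n_family_planted']} of them in the {summary['family_size']}-gene family"
)
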