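"""Shared plumbing for the analysis drivers.

The drivers operate on one synthetic study dataset emulating the design:
14 glioma cell lines (7 adherent, 7 stem) sequenced VPA-naive and
VPA-treated, 5,000 genes, a 30-gene family with 12 members planted as
up-regulated and promoter-euchromatinized.  The dataset is regenerated
deterministically (seed 17) under scratch/ on first use; small summary
tables land in results/.
"""

from pathlib import Path

from vpaglio.simulate import simulate_dataset

ROOT = Path(__file__).resolve().parent.parent
DATASET = ROOT / "scratch" / "analysis" / "dataset"
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"
SEED = 17


def dataset_dir() -> Path:
    """Simulate the study dataset if it is not already on disk."""
    if not (DATASET / "truth.json").exists():
        print(f"simulating study dataset (seed {SEED}) -> {DATASET}")
        simulate_dataset(DATASET, seed=SEED, n_genes=5000)
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return DATASET
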