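#!/usr/bin/env python
"""Run the full discovery pipeline on the simulated study and inspect what it found.

Scores pathways (PAS), screens them against overall survival, decomposes
crosstalk, filters sub-pathway features at FDR < 0.01, intersects across the
two largest cohorts into the final feature panel, clusters the primary
cohort's training split (4:1) into G1/G2 subtypes, and trains the KNN
classifier.  Writes the manifest, the panel, the per-k clustering
diagnostics and the training/held-out evaluations to results/discovery/.
"""

import json
from pathlib import Path

from crosspas.cli import write_discovery_artifacts
from crosspas.study import run_synthetic_study

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "discovery"
MODEL_OUT = ROOT / "scratch" / "discovery"  # full model blobs (regenerable)


def main() -> None:
    outcome = run_synthetic_study(SEED)
    result = outcome.result
    write_discovery_artifacts(result, MODEL_OUT)
    OUT.mkdir(parents=True, exist_ok=True)
    for small in ("manifest.json", "panel.tsv", "panel.gmt", "predictions.tsv"):
        (OUT / small).write_text((MODEL_OUT / small).read_text())
    result.subtype_model.diagnostics.to_csv(
        OUT / "k_diagnostics.tsv", sep="\t", index=False)
    truth_metrics = {
        "selected_k": outcome.k_selected,
        "training_ari_vs_planted_truth": outcome.ari_training,
        "heldout_subtype_accuracy": outcome.heldout_accuracy,
        "heldout_logrank_p": outcome.heldout_logrank_p,
        "external_accuracy": outcome.external_accuracy,
    }
    (OUT / "truth_recovery.json").write_text(
        json.dumps(truth_metrics, indent=1, sort_keys=True))

    print(f"panel ({len(result.panel_ids)} features): {result.panel_ids}")
    print(f"selected k = {outcome.k_selected}; "
          f"training ARI vs planted truth = {outcome.ari_training:.3f}")
    print(f"held-out accuracy = {outcome.heldout_accuracy:.3f}, "
          f"log-rank p = {outcome.heldout_logrank_p:.2e}")
    print(f"10-fold CV accuracy = {result.cv['accuracy_mean']:.3f}")
    print(f"tables -> {OUT}; full model artifacts -> {MODEL_OUT}")


if __name__ == "__main__":
    main()
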