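"""AMR-vs-rest penalized classification and cross-panel transfer.

Trains an L1-penalized logistic model on each panel (near-zero-variance
and correlation filters, 10-fold cross-validated penalty), reports pooled
out-of-fold ROC performance, then applies the small-panel model to the
large panel's cohort by gene symbol.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, processed

from ncounter_reject._utils import derive_seed
from ncounter_reject.classify import (
    amr_labels,
    cv_evaluate,
    train_panel_classifier,
    transfer_evaluate,
)


def main():
    norms, models = {}, {}
    for name in ("large_panel", "small_panel"):
        _, _, _, _, norm = processed(name)
        norms[name] = norm
        seed = derive_seed(SEED, f"classifier:{name}")
        model, x_f = train_panel_classifier(norm, seed=seed)
        models[name] = model
        out = RESULTS / name
        out.mkdir(parents=True, exist_ok=True)
        model.to_json(out / "model.json")
        result = cv_evaluate(x_f, amr_labels(norm.samples),
                             lambda_=model.lambda_, seed=seed)
        with open(out / "cv_eval.json", "w") as fh:
            json.dump(result.summary(), fh, indent=1, sort_keys=True)
        print(
            f"{name}: lambda = {model.lambda_:.4g}, {len(model.coefficients)} "
            f"signature genes, CV AUC = {result.auc:.3f} "
            f"(sens {result.sensitivity:.3f} / spec {result.specificity:.3f})"
        )

    transfer = transfer_evaluate(models["small_panel"], norms["large_panel"])
    with open(RESULTS / "transfer_eval.json", "w") as fh:
        json.dump(transfer.summary(), fh, indent=1, sort_keys=True)
    print(
        f"small-panel model on large-panel cohort: AUC = {transfer.auc:.3f} "
        f"(sens {transfer.sensitivity:.3f} / spec {transfer.specificity:.3f})"
    )


if __name__ == "__main__":
    main()
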