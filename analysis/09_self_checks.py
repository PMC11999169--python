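"""Oracle-backed self-checks of the analysis machinery: resampling
moments vs the hypergeometric closed form, the Steiner-forest heuristic
vs exhaustive enumeration, planted-effect recovery, QC recovery, and
pipeline determinism.

Writes self_checks.json. The same experiments back the acceptance script.
"""

import json
import tempfile
from pathlib import Path

from kinopipe import experiments

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    checks = {
        "krsa_convergence": experiments.krsa_convergence(seed=SEED),
        "pcsf_oracle": experiments.pcsf_oracle(seed=SEED),
        "planted_recovery": experiments.planted_recovery(seed=SEED),
        "qc_recovery": experiments.qc_recovery(seed=SEED),
        "ora_enumeration": experiments.ora_enumeration_check(seed=SEED),
    }
    with tempfile.TemporaryDirectory() as tmp:
        checks["pipeline_determinism"] = experiments.pipeline_determinism(
            tmp, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "self_checks.json").write_text(json.dumps(checks, indent=1) + "\n")
    for name, res in checks.items():
        print(f"{name}: {res}")


if __name__ == "__main__":
    main()
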