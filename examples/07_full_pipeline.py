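"""One-command end-to-end run: simulate -> localize -> patterns -> transfer
-> drop -> cluster -> behavior, with a reproducible run directory.

Equivalent shell usage:
    compdrop run --config examples/pipeline_config.yaml --out runs/demo
"""

import warnings

warnings.filterwarnings("ignore")

from compdrop import RunConfig, make_report, run_pipeline

config = RunConfig(
    seed=5,
    simulate=dict(
        n_subjects=5,
        n_channels=12,
        sampling_rate=128.0,
        epoch_span=(-100.0, 700.0),
        n_categories=5,
        n_exemplars_per_category=4,
        n_items_s2=24,
        signal_window=(80.0, 400.0),
        effect_size=2.0,
    ),
    step_ms=40.0,
    localizer_n_perm=25,
    cluster_n_perm=150,
    n_boot=10,
    boot_n_perm=100,
    behavior_n_perm=50,
)
out = run_pipeline(config, "runs/demo")
print(make_report(out))
print(f"Stage outputs (TSV tables, summary.json, run.log) are in {out}/")
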