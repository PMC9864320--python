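"""The fixed-labeled / growing-unlabeled experiment grid.

Reproduces, at desk scale, the protocol of holding a small labeled pool
fixed while growing the unlabeled pool, with a supervised-only baseline
row of equal training budget.  Expect a couple of minutes on one CPU.
"""

import lesionseg as ls

report = ls.run_protocol(
    labeled_n=10,
    unlabeled_ns=[20, 50],
    phantom=ls.PhantomConfig(n_unlabeled=50, n_test=20, seed=0),
    config=ls.TrainConfig.tiny(seed=0, val_every=0),
)
print(report)
# Rows are labeled/unlabeled ratios; columns the five metrics as
# "mean ± SD" over the shared 20-image test set. At this scale the
# arms differ by fractions of a DSC point — the adversarial term is
# deliberately small (λadv = 0.01) relative to the supervised loss.
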