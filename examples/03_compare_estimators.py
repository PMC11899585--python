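"""Monte-Carlo comparison of the CNN estimator with the two baselines.

Runs a few replicates of a *non-linear* feature-network scenario at small
scale and prints bias and SD of the NIE for each method.  The
principal-component baseline assumes linear feature-mediator maps, so its
bias grows under non-linearity while the CNN adapts — the pattern this
method exists to demonstrate.
"""

import medcnn

config = medcnn.make_scenario(
    "alternative", beta1_override=5.0, n=600,
    network_sizes=(40, 50, 40), feature_map="nonlinear", seed=0,
)

report = medcnn.run_simulation(
    config, reps=3, methods=("med_cnn", "sd_based", "reg_based"),
    master_seed=11,
    fit_options=dict(epochs_init=40, epochs=8, max_iter=2,
                     learning_rate=5e-3, batch_size=96, patience=4),
)

print(f"true NIE = {config.true_nie} (n={config.n}, {report.reps} replicates)")
print(f"{'method':<10} {'bias':>8} {'SD':>8}")
for m in report.methods:
    s = report.nie[m]
    print(f"{m:<10} {s.bias:>8.2f} {s.sd:>8.2f}")
print("bias = mean(NIE estimates) - truth; SD = spread across replicates")
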