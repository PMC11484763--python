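"""Federated training when every site shuffles its feature columns.

Four synthetic sites share a latent risk signal but store their features in
different column orders.  Plain federated averaging mixes incompatible
updates; the knowledge-filtering framework lets each site keep its own
view and still train one global model.  (Scaled down for a quick demo —
the full study conditions live in the test suite.)
"""

from fedfilter import ExperimentConfig, SyntheticSpec, run_scenario_experiment

spec = SyntheticSpec(samples_per_client=(600, 600, 600, 150))
cfg = ExperimentConfig(rounds=40, standalone_epochs=40)

for scenario in ("standard", "shuffled"):
    reports = run_scenario_experiment(scenario, ["proposed", "fedavg"], spec,
                                      n_runs=2, config=cfg, base_seed=0)
    for method, rep in reports.items():
        m = rep.macro_mean
        print(f"{scenario:9s} {method:9s} macro AUROC {m['auroc']:.3f} "
              f"AUPRC {m['auprc']:.3f}")
print("\nThe proposed method's AUROC should barely move between the two")
print("scenarios, while FedAvg drops when the views are shuffled.")
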