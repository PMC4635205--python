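"""Integrated model: network contagion governed by a capacity-limited policy.

Compares the adopted fraction with no policy, a weak policy and a strong
policy on the same contact network.
"""

from behaviordyn.networks import generate_poisson_graph
from behaviordyn.policy import PolicyConfig, run_integrated_model

graph = generate_poisson_graph(500, 0.01, seed=3)
common = dict(transmit_prob=0.3, spontaneous_prob=0.002,
              initial_adopters=[0], t_steps=60, seed=11)

for label, policy in [
    ("no policy", PolicyConfig(output_threshold=1.5, service_capacity=0, success_prob=1.0)),
    ("weak policy (2 requests/step)", PolicyConfig(0.5, 2, 0.7)),
    ("strong policy (25 requests/step)", PolicyConfig(0.5, 25, 0.9)),
]:
    df = run_integrated_model(graph, policy=policy, **common)
    print(f"{label}: final adopted = {df['adopted'].iloc[-1]}/500, "
          f"peak queue = {df['queue_length'].max()}, "
          f"total reversions = {df['reversions'].sum()}")
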