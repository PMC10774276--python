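"""Communication accounting: prediction sharing vs parameter averaging.

FedAvg moves the full parameter vector up and down for every client
every round; federated distillation moves a few bytes per shared
prediction.
"""

import selectivefd as sfd

K, C, T, P = 10, 10, 8, 10**5
fedavg = sfd.comm_bytes("fedavg", C=C, shared_counts=[], parameter_count=P, K=K, T=T)
fd = sfd.comm_bytes(
    "fd-soft", C=C, shared_counts=[(500, 500)] * T, parameter_count=0, K=K, T=T
)

fa_round = int(fedavg.loc[0, "bytes_up"] + fedavg.loc[0, "bytes_down"])
fd_round = int(fd.loc[0, "bytes_up"] + fd.loc[0, "bytes_down"])
print(f"FedAvg, {P} parameters: {fa_round/1e6:.1f} MB per round (all clients)")
print(f"FD soft labels, 500 shared predictions: {fd_round/1e6:.3f} MB per round")
print(f"ratio: {fa_round/fd_round:.0f}x")
print(f"per client, FedAvg exchanges {2*4*P/1e3:.0f} kB vs "
      f"{500*(4+4*C)/1e3:.0f} kB of ensemble downloads: "
      f"{2*4*P/(500*(4+4*C)):.1f}x")
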