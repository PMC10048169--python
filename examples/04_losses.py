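"""The joint objective: focal classification loss + cosine contrastive term.

Demonstrates the identities that pin the loss down: the contrastive term for
identical / orthogonal / opposite branch maps, and the focal-to-cross-entropy
reduction at gamma = 0.
"""

import numpy as np

from dual_atme import LossConfig, contrastive_loss, focal_loss, joint_loss

a = np.array([1.0, -1.0, 1.0, -1.0])
b = np.array([1.0, 1.0, -1.0, -1.0])
print("contrastive loss  (identical) :", contrastive_loss(a, a))
print("contrastive loss (orthogonal) :", contrastive_loss(a, b))
print("contrastive loss   (opposite) :", contrastive_loss(a, -a))

probs = np.array([0.7, 0.2, 0.1])
print(f"\nfocal loss, p_y=0.7, gamma=2  : {focal_loss(probs, 0):.6f}"
      f"  (= -(0.3^2) ln 0.7 = {-(0.3 ** 2) * np.log(0.7):.6f})")
print(f"focal loss, gamma=0           : {focal_loss(probs, 0, LossConfig(focal_gamma=0)):.6f}"
      f"  (= cross-entropy = {-np.log(0.7):.6f})")

total, comps = joint_loss(probs, 0, a, b, LossConfig(lam=0.01))
print(f"\njoint loss, lambda=0.01       : {total:.6f} "
      f"(cls {comps['cls']:.6f} + 0.01 x con {comps['con']:.6f})")
print("\nThe small lambda keeps classification dominant; the contrastive term")
print("only nudges the two branch embeddings of the same sample together.")
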