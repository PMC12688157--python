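"""A tour of the geometry kernels behind the structural energy terms.

Each kernel is evaluated on a small constructed geometry whose exact
value is known, so the printed numbers double as a sanity check:
solvent-accessible surface area, optimal superposition RMSD,
secondary-structure assignment, centroid separation, globularity and
ring symmetry.

Run:  python examples/04_energy_term_tour.py
"""

import math

import numpy as np

from foldscape import energies as en

# --- SASA: isolated sulfur atom has the closed-form area 4*pi*(r+probe)^2
area = en.shrake_rupley_sasa(np.zeros((1, 3)), ["S"], probe_radius=1.4,
                             n_points=1000)[0]
print(f"SASA of isolated S    : {area:8.2f} A^2   "
      f"(closed form {4 * math.pi * 3.2**2:.2f})")

# --- superposition: a rotated+translated cloud aligns back to RMSD ~ 0
rng = np.random.default_rng(0)
cloud = rng.normal(scale=4, size=(10, 3))
theta = 0.8
rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
moved = cloud @ rot.T + [5.0, -3.0, 2.0]
_, _, rmsd = en.optimal_superposition(cloud, moved)
print(f"superposition RMSD    : {rmsd:8.2e} A     (rigid copy -> 0)")

# --- secondary structure: ideal helical Ca trace
n = 12
t = np.deg2rad(100.0) * np.arange(n)
helix = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)], axis=1)
labels = en.assign_secondary_structure(helix)
print(f"helix trace labels    : {''.join(lab[0] for lab in labels)}   "
      "(h = helix, interior residues)")

# --- separation: centroids at the 3-4-5 triangle
print(f"separation energy     : "
      f"{en.separation_energy(np.zeros((1, 3)), np.array([[3.0, 4.0, 0.0]])):8.2f} A")

# --- globularity: collinear atoms at -3,-1,1,3 have distance spread 1
collinear = np.array([[-3.0, 0, 0], [-1.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
print(f"globular energy       : {en.globular_energy(collinear):8.2f} A")

# --- ring symmetry: unit square is perfect for neighbours, not all pairs
square = [np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]),
          np.array([[1.0, 1, 0]]), np.array([[0.0, 1, 0]])]
print(f"square, neighbors     : {en.ring_symmetry_energy(square, 'neighbors'):8.4f} A")
print(f"square, all pairs     : {en.ring_symmetry_energy(square, 'all_pairs'):8.4f} A "
      "(sides vs diagonals)")
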