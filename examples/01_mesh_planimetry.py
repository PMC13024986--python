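"""Measure curved surface area on a triangulated mesh.

Builds a cylindrical "limb" surface, checks the triangle-sum area
against the analytic lateral area, and round-trips it through an ASCII
PLY file.
"""
import math
import tempfile
from pathlib import Path

from woundmetry import SyntheticScene, make_anatomy, read_mesh, surface_area, write_mesh

scene = SyntheticScene("cylinder_limb", {"radius": 40.0, "length": 200.0})
mesh = make_anatomy(scene)

analytic = 2 * math.pi * 40.0 * 200.0 / 100.0  # lateral area, cm2
measured = surface_area(mesh)
print(f"cylinder limb: {mesh.n_faces} triangles")
print(f"analytic lateral area : {analytic:10.3f} cm2")
print(f"triangle-sum area     : {measured:10.3f} cm2")
print(f"relative error        : {abs(measured - analytic) / analytic:10.2e}")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "limb.ply"
    write_mesh(path, mesh)
    back = read_mesh(path)
    print(f"after PLY round-trip  : {surface_area(back):10.3f} cm2")

# The triangle sum converges to the true curved area from below (chords
# undercut arcs); at the default 1 mm edge length the gap is ~1e-5.
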