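# maskfit

Geometric prediction of how well a tight-fitting filtering-facepiece
respirator (FFP3/N95 class) fits an individual face, from 3D surface
scans alone.

A respirator only protects if it seals around the nose and mouth, but
commercial devices come in few sizes and fit different faces very
differently. Given surface meshes of a face (with and without the
respirator worn) and of the respirator's internal surface, `maskfit`

1. rigidly aligns all scans into a common reference-head frame
   (iterative closest point, ICP);
2. deforms the respirator's internal surface toward the face over a
   ladder of eight stiffness levels δ₁…δ₈ (non-rigid ICP: δ₁ conforms
   almost fully, δ₈ is near rigid);
3. scores each registration from the signed respirator–face distance
   *d* per vertex: **gap** (*d* > 0 mm), **adequate seal**
   (−3 ≤ *d* ≤ 0 mm), **indentation** (*d* < −3 mm), and **conformity**
   (|*d*| ≤ 1 mm), all as area-weighted percentages;
4. selects the optimum δ as the level combining maximum conformity with
   a narrow central-95% distance interval;
5. quantifies facial soft-tissue displacement between the loaded and
   unloaded scans (2.5th/97.5th percentiles of signed loaded-to-unloaded
   distance); and
6. correlates fit percentages with facial anthropometrics (bio-ocular
   width, alar width, dorsal nasal length, lower-third facial height)
   via Shapiro–Wilk checks and Pearson correlation.

No clinical scans ship with the package; a deterministic synthetic-scene
generator (`maskfit.scenes`) builds face/respirator/loaded-face triplets
with known ground truth (prescribed indentation and bulge fields,
recorded rigid misalignments, analytic landmarks) so that every stage is
testable end to end.

## Worked example

Generate a synthetic subject and run the δ sensitivity sweep:

```bash
maskfit synth --out demo --seed 1
maskfit sweep \
  --unloaded-face demo/unloaded_face.stl \
  --loaded-face demo/loaded_face.stl \
  --respirator-whole demo/respirator_whole.stl \
  --respirator-internal demo/respirator_internal.stl \
  --reference-head demo/reference_head.stl \
  --reference-head-with-respirator demo/reference_head_with_respirator.stl \
  --out demo/sweep
maskfit displacement --unloaded-face demo/unloaded_face.stl \
  --loaded-face demo/loaded_face.stl --out demo/disp
```

which prints

```
optimum: delta5 (conformity 84.2%)
soft-tissue displacement: -4.90 mm (2.5th pct) to +3.91 mm (97.5th pct)
```

and writes `demo/sweep/sweep.csv`:

```
 level  pct_gap  pct_indent  pct_seal  pct_conform  ci_width
delta1     51.6         0.8      47.5         84.1       5.8
delta2     51.7         0.8      47.5         84.1       5.8
delta3     50.9         0.9      48.3         84.1       5.8
delta4     57.3         0.9      41.9         84.1       5.8
delta5     55.0         0.9      44.1         84.2       5.8
delta6     63.2         1.1      35.7         81.1       6.1
delta7     69.3         1.3      29.4         70.2       6.1
delta8     69.3         1.3      29.4         70.1       6.1
 rigid     69.3         1.3      29.4         70.1       6.1
```

Reading the table: softer deformation levels conform better to the
loaded face (84% of the respirator area within ±1 mm at δ₁–δ₅, falling
to 70% for the rigid registration); the optimum (δ₅) combines maximal
conformity with the narrowest central-95% distance interval. The
displacement line recovers this scene's prescribed 5 mm cheek
indentation and 4 mm lateral bulge from the loaded/unloaded scan pair
alone. The scene's ~50% gap area comes from its deliberately gapped
nose-bridge standoff and the prescribed loading; the deep-indentation
area stays near 1%, so most contact is in the adequate-seal band.

The same pipeline runs on real STL scans by substituting file paths;
`maskfit fit --level delta5 ...` then reports the final goodness-of-fit
prediction on the unloaded face, and `maskfit anthro` correlates
per-subject fit percentages with landmark-derived anthropometrics.

As a library, the registration core is exposed as scikit-learn style
estimators (`RigidICP`, `NonRigidICP` with `fit`/`transform`/
`get_params`), with module-level functions (`icp_align`,
`nonrigid_icp`, `run_delta_sweep`, …) wrapping them.

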