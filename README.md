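# careg — probabilistic and geometric anatomical mapping

`careg` registers two anatomies that are each represented *jointly* by
tissue class-posterior probability images and boundary surfaces.  The
motivating application is early brain development: between a neonatal and
a 2-year MRI scan, white matter changes appearance so drastically
(myelination) that raw intensities are not comparable, while tissue
*posteriors* (p_wm, p_gm, p_csf) and tissue *boundaries* still are.  The
package is aimed at researchers who already have tissue posteriors (from
any segmentation tool) and want a deformable mapping that respects both
compartments, and at method developers who need a tested reference for
currents-based surface matching with a particle-mesh backend.

## The model

An anatomy is the tuple

    A = { p_c=1(x), ..., p_c=Nc(x),  M_1, ..., M_Ns },

class posteriors on a voxel lattice plus oriented triangle meshes in the
same physical frame.  Registration estimates a diffeomorphism h
minimizing

    E(h) = w_p Σ_c ∫ |p1,c ∘ h⁻¹ − p2,c|² dx
         + w_g Σ_j ‖[h(M1,j)] − [M2,j]‖²_k ,

where the second term is the **currents** distance: a surface is encoded
as one vector-valued Dirac mass per face — the area-weighted normal
η(f) = ½(x_s−x_r)×(x_t−x_r) at the centroid c(f) — and

    ‖[M]‖²_k = Σ_f Σ_f' ⟨η(f), η(f')⟩ k(c(f), c(f')),

with a Gaussian or Cauchy kernel k of width σ.  The distance between two
surfaces is the norm of their union with one side negated, so no point
correspondence is ever required; curves (tangents) and point sets use the
same bilinear form.

The transformation is built greedily: each iteration solves the fluid PDE
L v = F with L = −α∇² − β∇(∇·) + γ in the Fourier domain, where F
combines the image body force (posterior difference × posterior gradient)
and the splatted currents gradient; images compose the inverse map
(backward mapping, no holes) while meshes integrate forward along +v.
A kernel-width schedule (large σ first, then smaller) gives multiscale
behaviour without ever resampling the grid.

The all-pairs currents sums are O(N²); the **particle-mesh** (PM) backend
reduces them to O(M log M) by splatting the face momenta onto the image
lattice with trilinear weights, convolving with the kernel via FFT
(with cloud-in-cell window deconvolution), and interpolating back at the
centroids.  The exact O(N²) implementation is retained as the oracle.

## Worked example

Synthetic phantoms make the package fully testable without data:

```bash
careg make-phantom --spec spec.yaml --out moving --deform translation --magnitude 2.0
careg register --moving-anatomy moving --target-anatomy moving_deformed \
               --config cfg.yaml --out reg
careg norm --mesh-a moving/surface_tissue.vtk \
           --mesh-b moving_deformed/surface_tissue.vtk --sigma 6 --pm
```

with `spec.yaml` describing a radius-8 sphere on a 32³ grid and
`cfg.yaml` a single σ = 6 stage of 15 iterations.  On this example the
register command prints

```
stage 0: min Jacobian determinant 0.5769
final energy 9.46421 after 13 iterations
```

i.e. the mapping stayed diffeomorphic (positive Jacobian determinant
everywhere) and the combined energy fell from its initial value to 9.5;
`reg/` contains the displacement field (NIfTI), the deformed posteriors
and surfaces, and the per-iteration energy trace (CSV).  The `norm`
command prints the squared currents dissimilarity of the two surfaces —
`8142.45` with the particle-mesh backend versus `8120.10` exact, a 0.3 %
approximation error.

The same pipeline is available as a library:

```python
from careg import RegistrationConfig, Stage, register, overlap, map_labels
from careg.phantoms import PhantomSpec, make_phantom, \
    make_ground_truth_deformation, deform_phantom
```

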