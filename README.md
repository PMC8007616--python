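# spinemech

Mechanics of dendritic-spine membranes on triangle meshes.

Dendritic spines — the micron-scale protrusions that carry most excitatory
synapses — enlarge when a synapse is potentiated (LTP), driven by actin
polymerization pushing against the plasma membrane. `spinemech` is a
vertex-based simulator of that process for computational neuroscientists
and membrane biophysicists: it evolves a closed triangulated membrane under
a Helfrich-type energy and a continuous actin-polymerization force, tracks
the force generated by membrane tension at Lagrangian probe points (the
proposed mechanical trigger for exocytosis), and implements the post-LTP
procedures of omega-profile fusion and PSD-growth stabilization.

## Model

Vertex dynamics are the overdamped gradient flow

    dx_k/dt = zeta * ( F_mem(x_k) + F_actin(x_k) )

where `F_mem = -dE_mem/dx_k` is the exact analytic gradient of the discrete
membrane energy

    E_mem = P*V + sigma*A + 2*kappa * integral (c1+c2)^2 dA

(pressure-volume and tension-area penalties plus total-curvature Helfrich
bending), and the actin force from polymerization focus `f_i` is

    F_actin(f_i, x_k) = alpha * phi(n_f)/d(f_i, x_k) * unit(x_k - f_i),
    phi = n_fil / (n_vertices0 * n_f).

PSD disc and neck vertices are fixed. Integration is classical RK4 at
`dt = 1/8 s` with per-step isotropic remeshing (Botsch–Kobbelt-style
split/collapse/flip/tangential-relax at target edge `delta_s = 0.03` um).
The tension force at a tracking point is `-d(sigma*A)/dx_j` measured on a
coarse probe mesh of spacing `2*delta_s`. All defaults are the reference
parameter set of the underlying spine study; see `docs/methods.md` for the
full account, numerical choices and known quantitative deviations.

## Worked example

```python
from spinemech import ModelParams, find_resting_shape
from spinemech.scenarios import make_ltp_state, run_ltp
from spinemech.engine import detect_t_star_max_probe
from spinemech.stats import tension_summary

params = ModelParams()
resting = find_resting_shape(params)        # ~1-2 min
print(f"resting: {resting.n_vertices} vertices, "
      f"V = {resting.enclosed_volume():.4f} um^3")

state = make_ltp_state(resting, params, "near_psd")   # one focus at the PSD
series = run_ltp(state, duration=120.0)               # LTP expansion
t_star, k, probe = detect_t_star_max_probe(series, fold=2.5)
ts = tension_summary(series.norms_arr[k])
print(f"t* = {t_star:.1f} s  v* = {series.volume[k]:.4f} um^3")
print(f"tension sum {ts.total:.1f} pN, skewness {ts.skewness:.2f}")
```

prints (resting relaxation is deterministic, so exactly):

```
resting: 1175 vertices, V = 0.0778 um^3
t* = 42.4 s  v* = 0.1130 um^3
tension sum 128.1 pN, skewness 0.79
```

meaning: with the tabulated parameters the spine settles at a resting
volume of 0.078 um^3; a single near-PSD polymerization focus expands it,
and after ~42 s the leading tension probe has risen 2.5-fold over its
resting baseline — the membrane-tension signal proposed to trigger
exocytosis — at which point the spine has grown ~45% in volume and the
probe-tension distribution is right-skewed (the hallmark of a single
localized focus; evenly spread foci give flatter distributions).

The same pipeline is scriptable from the shell:

```bash
spinemech rest --out resting.ply
spinemech run --resting resting.ply --foci near_psd --out run/
spinemech preset configs/fig2_foci_22.yaml --resting resting.ply
spinemech exo --resting resting.ply --mode tip_focus
spinemech stabilize --resting resting.ply
spinemech stats run/
```

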