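# Methods

`dhaflux` couples two models of *Crypthecodinium cohnii* central carbon
metabolism to compare glucose, glycerol and ethanol as feedstocks for
docosahexaenoic acid (DHA, C22:6) production: a pathway-scale kinetic ODE
model of substrate uptake and acetyl-CoA supply, and a medium-scale
constraint-based stoichiometric model with a biomass equation and a DHA
overproduction sink. This note records the models, their assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## 1. The kinetic model

**Scope.** Three compartments (extracellular, cytosol, mitochondria; the
mitochondrial volume is 1% of the cytosolic volume). 35 reactions over 36
metabolites: the three substrate uptakes; glycolysis from hexokinase to
pyruvate kinase; the glycerol entry route (glycerol kinase,
glycerol-3-phosphate dehydrogenase); the ethanol route (alcohol and
acetaldehyde dehydrogenases, acetate-CoA ligase); the TCA cycle with pyruvate
dehydrogenase (PDH), pyruvate carboxylase (PYC) and malic enzyme; ATP-citrate
lyase (ACL) in the cytosol; pyruvate, acetate, citrate and oxaloacetate
shuttles; and a cytosolic acetyl-CoA sink standing for fatty-acid synthesis.
There is no pentose phosphate pathway and no energy/redox cofactors. CO2 and
bicarbonate are boundary species so every (de)carboxylation balances carbon
exactly; carbon conservation of all 35 reactions is a test surface.

**Rate laws.** The observables this model exists to reproduce are
steady-state fluxes, which are fixed by stoichiometry and the fitted maximal
rates rather than by rate-law fine structure. We therefore use deliberately
uniform forms: constant flux for substrate uptake (a single,
concentration-independent uptake rate per scenario), irreversible
Michaelis-Menten for committed steps, and reversible Michaelis-Menten with a
Haldane constraint for interior steps. Defaults: Km 0.1 mmol/L (enzymes),
1.0 mmol/L (carriers), Keq 1, Vm 50 mmol/min/L. Two structural exceptions
keep the TCA cycle functional out of the box: citrate synthase operates at
low oxaloacetate (Km_oaa 0.005 mmol/L, Vm 150) and the anaplerotic drain via
malic enzyme is small (Vm 2); without these the C4 pool starves and
acetyl-CoA diverges. Every enzymatic rate also carries a dimensionless
overexpression coefficient k (default 1 = wild type).

**Scenarios.** One parameter set serves glucose and glycerol
(PDH Vmax = 907 mmol/min/L); ethanol requires a second parameterization with
PDH effectively off (Vmax = 1e-6), because the ethanol route supplies
mitochondrial acetyl-CoA directly and all pyruvate must regenerate
oxaloacetate. At the ethanol steady state the PDH flux is < 1e-4 of the
citrate synthase flux.

**Units.** Concentrations are mmol/L per compartment; all fluxes are amount
rates per litre of cytosol (mmol/min/L), so mitochondrial and cytosolic
rates are directly comparable and match the volumetric unit of the flux
datasets.

**Steady states.** Long-horizon stiff integration (LSODA) with a
divergence guard, followed by a Newton polish of the flux balance; tolerance
1e-8 mmol/L/min on max |dC/dt|. Newton roots are accepted only if the local
Jacobian has no eigenvalue with positive real part, so the fast
(Newton-first) path used inside fitting agrees with what integration finds.
Steady states are initial-condition robust (tested by perturbing the default
0.1 mmol/L start by x10 and /10).

## 2. Calibration

**Data.** Three packaged flux datasets (TSV fixtures), one per substrate,
anchored by the measured values: uptake 3.58 and ACL 3.87 mmol/min/L for
glucose (13C-derived), uptake 2.42 / ACL 1.44 for glycerol, uptake 7.76 /
ACL 4.76 and TCA flux 3.00 for ethanol. Entries flagged `synthetic` follow
from the network's carbon identities rather than measurement.

**Carbon identities.** In this PPP-free topology the steady-state cycle flux
is not a free quantity: with all glucose carbon entering glycolysis,
aconitase flux = 2 x uptake − ACL (glucose/glycerol) and uptake − ACL
(ethanol). The published ethanol triple satisfies its identity exactly and
the glycerol triple to within 9%, but the published glucose TCA flux
(2.43 mmol/min/L) is carbon-infeasible here (the identity forces 3.29): the
13C study it derives from included pentose phosphate and biosynthetic
branches that this reduced model deliberately omits. The glucose and
glycerol TCA entries are therefore recorded in the fixtures with weight 0 —
kept as data, excluded from the objective — and the calibration anchors are
the uptake and ACL fluxes, the quantities the analysis actually consumes.

**Objective and optimizer.** Relative weighted SSE over steady-state fluxes,
plus smooth quadratic penalties (weight 1e3) for internal concentrations
above 12 mmol/L (cellular ethanol: 32 mmol/L) and a large finite penalty for
parameter sets without a stable steady state. Differential evolution over
log10 parameters (seeded; the initial population is anchored at the current
working parameter set) followed by Nelder-Mead refinement; best of n_starts.
Glucose and glycerol are fitted jointly with one parameter set; ethanol
separately. The packaged calibration frees the Vm of the branch-point
reactions (aconitase, citrate exporter, ACL, malate dehydrogenase, malic
enzyme, PYC, citrate synthase, the acetyl-CoA sink) plus the citrate
affinities of aconitase and the citrate exporter — the citrate node is the
one branch whose operating point differs between the two jointly fitted
scenarios, so its saturation behaviour is both identifiable and needed. An
optional total-Vm budget (an enzyme-amount constraint) is available but off
by default; no number is published for it.

With the packaged settings the joint fit reproduces both ACL anchors to
within a few percent (often exactly); the fitted glucose scenario's ACL flux
is the headline kinetic result (3.87 mmol/min/L at uptake 3.58, i.e. 36% of
glucose carbon to acetyl-CoA).

## 3. The stoichiometric model

**Scope.** A reduced reconstruction (95 reactions, 83 metabolites, 3
compartments) rather than the full deposited-scale model: glycolysis and
gluconeogenesis (FBPase, PEP carboxykinase), the pentose phosphate pathway,
the TCA cycle with both NAD- and NADP-linked isocitrate dehydrogenase and
malic enzyme, the glyoxylate shunt, the lipogenic citrate-malate cycle (ACL,
cytosolic malate dehydrogenase, cytosolic NADP-malic enzyme — the canonical
acetyl-CoA/NADPH supply of oleaginous heterotrophs), explicit
ATP/NADH/NADPH/FADH2 bookkeeping with lumped oxidative phosphorylation,
lumped macromolecule synthesis, a biomass equation, a DHA synthesis/export
route, and 35 transport/exchange reactions (uptakes for
glucose/glycerol/ethanol/acetate plus O2, CO2, H2O, H+, ammonia, phosphate,
DHA). The full kinetic subnetwork is embedded under identical reaction ids
(the lumped acetyl-CoA sink maps to the fatty-acid synthesis entry). CO2
exchange is efflux-only, so the model cannot grow on external CO2. All
internal reactions conserve carbon exactly (tested); flux unit mmol/gDW/h.

**Biomass.** Default composition per gram dry weight: protein 0.45,
carbohydrate 0.25, lipid 0.20 (of which DHA 0.035), RNA 0.06, DNA 0.01, ash
0.03 — fully overridable. Monomer pseudo-metabolites carry integer carbon
counts (protein residue C5, mass 110 g/mol; carbohydrate unit C6;
triacylglycerol C51; RNA/DNA residue C10), giving a biomass carbon content
of 44.7 mmol C/gDW and a mass closure of 970 mg/gDW (ash excluded; checked
at 1000 +- 5%). Growth-associated maintenance is 1 mmol ATP/gDW; the lumped
synthesis reactions carry modest explicit ATP/NADPH costs because they
compress multi-step pathways.

**Two deliberate efficiency routes.** A naive reconstruction pays one CO2
for every cytosolic acetyl unit (obligatory PDH decarboxylation) and one CO2
for every C3 unit made from C2 substrates, which puts the optimal carbon
demand ~20% above the published substrate-independent optimum of about
42 mmol C1 per gDW. The published behaviour implies the reference model
supplies acetyl and C3 units without committed carbon loss, so this
reconstruction includes (i) the phosphoketolase shunt (phosphoketolase +
acetate kinase): sugar-phosphate carbon to acetyl without decarboxylation,
and (ii) a lumped reductive carboxylation of acetyl-CoA to pyruvate
("pyruvate synthase"), the lossless C2-to-C3 step required for the ethanol
and acetate optima. P/O ratios are the classic 3 (NADH) and 2 (FADH2). With
these choices the minimal carbon demand is 48.8 / 44.7 / 44.7 mmolC1/gDW for
glucose / glycerol / ethanol (4.2% coefficient of variation), inside the
published 42 +- 15% band; glycerol and ethanol are exactly carbon-limited
(optimum = biomass carbon content). Acetate remains dearer
(~57 mmolC1/gDW): its activation alone costs >= 1 ATP per 2 carbons, which
no honest energy bookkeeping can avoid — the model's maximal growth rate on
acetate (0.021 /h at 0.60 mmol/gDW/h) therefore sits ~16% below the reported
batch estimate while all other reported substrate/growth pairs are met or
exceeded.

**FBA.** Linear programs are solved with HiGHS; optimal solutions are
re-checked outside the solver (max |S v| <= 1e-9, bounds respected) and can
be canonicalized parsimoniously (minimum total |v| at the fixed optimum) so
degenerate optima do not leak solver arbitrariness into reports. The LP core
is verified in tests against exhaustive vertex enumeration on 100 seeded
small instances and against an independent COBRA implementation on the full
model.

**DHA potential.** DHA synthesis is lumped as
11 acetyl-CoA + 10 NADPH + 9 ATP -> DHA (C22), reflecting the
polyketide-synthase route's carbon accounting. The scan fixes the biomass
flux at a fraction f of the model's maximal growth rate and maximizes DHA
export. Carbon-to-DHA (% of substrate carbon, counting exported DHA)
increases strictly as f drops: 0% at f = 1.0 (the optimum is carbon-limited,
so nothing is left at maximal growth), ~16% at f = 0.8 and ~47% at f = 0.4
on glucose. The DHA share of total fatty acids — (exported + biomass DHA)
mass over all fatty-acid mass made per unit time, with the TAG acyl share at
3 x 256.4/807.3 — rises from 18% through 53% to 85%. The published bar
values (27-70% carbon, 39-81% of TFA) depend on the deposited full-scale
model and an unprinted TFA definition; here they are report-only
diagnostics, while the monotone trend is the tested claim.

## 4. Kinetic-stoichiometric coupling

`fluxbridge` pins a kinetic steady-state flux set (converted to mmol/gDW/h
by the factor 5.5 = 0.33 x 1000/60, from dry weight = 33% of wet weight at
1 g/mL) into symmetric relative bands, closes the other substrates'
transports, optionally leaves PGI/PFK/aldolase free (the kinetic model
carries no pentose phosphate flux), maximizes biomass, and declares the set
feasible if the achieved growth rate reaches the target within the band
(glucose 4%, glycerol 10%, ethanol 3%). Zero-valued entries get an absolute
band of tolerance x the median nonzero flux, since a relative band on zero
would pin the reaction exactly. On infeasibility a greedy single-constraint
relaxation ranking reports which pinned reaction unblocks the LP — the
automated version of discovering by hand which reactions need freeing.

The packaged validation tasks pin the measured/anchor subset per substrate,
not the full kinetic vector: the kinetic model's only carbon exits are CO2
and the acetyl-CoA sink, so its full steady state commits all carbon and can
never support biomass on top. For ethanol the ACL flux is additionally left
free: pinning the measured acetyl output together with the observed growth
rate over-commits carbon under the default biomass composition (a linear
carbon budget shows ~3.5 mmolC1/gDW/h demanded against ~2.9 supplied).
Verdicts with the packaged tasks: glucose feasible as supplied at 4%;
glycerol and ethanol feasible only with the pentose-phosphate relaxation
(ethanol without it reaches only mu ~= 0.024 of the required 0.046);
feasibility is monotone in the tolerance.

## 5. Growth and uptake estimation; carbon accounting

The specific growth rate is the least-squares slope of ln(biomass) vs time.
The window defaults to the longest contiguous span whose ln-linear R^2
clears a threshold with floor 0.98; on cleaner data the threshold tightens
toward the best long-span R^2 so that a long window cannot average across a
growth-phase transition (e.g. substrate exhaustion). The uptake rate q_s
regresses cumulative consumption (mmol/L) against integrated biomass
(gDW.h/L); within a clean exponential window the integral is taken as
(X - X0)/mu, which makes the estimator quadrature-free and exact on ideal
curves — both estimators recover the truth to 1e-6 at zero noise and to
better than 10% (median) at 5% multiplicative noise.

Carbon metrics: C1 uptake = carbons x molar uptake; percent of substrate
carbon to acetyl-CoA = 100 x 2 x v_ACL / C1 uptake; experimental carbon per
gram biomass = C1 uptake / mu; excess over the model optimum =
100 x (experimental/optimal - 1). All metrics commute with the 5.5 unit
conversion to 1e-12 relative.

## 6. Synthetic data

The batch-curve generator emulates the cultivation regime the estimators
face: exponential growth (mu defaults drawn from the observed 0.017-0.051 /h
range), substrate-proportional consumption, a hard exhaustion transition (no
death phase — only the exponential window is analyzed), and multiplicative
lognormal noise (unit mean, chosen because measurement error in densities
and HPLC concentrations is positive and roughly proportional). Generators
are deterministic under a seed and emit their ground truth. What passing
recovery tests show is that the estimators invert the assumed growth model
reliably at realistic noise; they do not certify behaviour under lag phases,
mixotrophy or death phases, which real curves may contain and the generator
deliberately omits.

## 7. Known limitations

- The kinetic rate-law forms and Km/Keq defaults are placeholders for
  unavailable enzyme-level data; only steady-state fluxes, not concentration
  trajectories, should be interpreted. Reported mitochondrial acetyl-CoA
  concentration orderings across substrates are diagnostics, not tested
  claims.
- The stoichiometric reconstruction is reduced (~95 reactions); quantities
  that depend on the full deposited network (exact DHA-scan bar heights,
  the exact "about 42" value) are reproduced as bands/trends, not digits.
- The phosphoketolase and reductive-carboxylation reactions are efficiency
  devices mirroring the reference model's behaviour; direct enzymatic
  evidence in *C. cohnii* is not established.
- Acetate growth is structurally below the single reported batch point, as
  discussed above.
- The LP big-M bound (1000 mmol/gDW/h) caps "unbounded" verdicts in
  pathological custom models.
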