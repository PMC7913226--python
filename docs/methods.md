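# Methods

## Scope and overall procedure

The package predicts drug exposure in malnourished children in two steps:
a non-malnourished virtual pediatric population is generated from embedded
reference physiology, and each individual's system parameters are then
multiplied by a set of physiological scaling parameters (PSPs) describing
one of three malnutrition levels. Because the malnourished arm of any
comparison is a scaled copy of the same individuals, exposure ratios
between arms isolate the effect of the body-composition change from
population sampling noise.

The central assumption of the translation is that malnutrition alters the
body composition of children and adults in the same proportional way: the
PSPs are derived from adult reference-study measurements and applied
unchanged to pediatric bodies. A second structural assumption is that
malnutrition changes organ sizes, hematology and plasma proteins but not
tissue composition (the fractions used for partition-coefficient
prediction), enzyme abundance per gram of organ, or gastrointestinal
function.

## Reference physiology

Virtual bodies are interpolated from a version-controlled age/sex grid of
ICRP-style reference values (anchor ages 0, 1, 5, 10, 15, 30 and 80
years): organ masses for seventeen compartments (thirteen perfused organs,
lung, and arterial/venous/portal blood), specific perfusion in L/h per kg
tissue, hematocrit, albumin, alpha-1-acid glycoprotein and a
kidney-mass-specific GFR. Child body weight and height follow a denser
grid anchored to growth-standard medians, so an unscaled reference child
sits near weight-for-height z = 0 by construction; fat is the residual
that closes the organ-mass sum against the reference body weight at every
age. Organ masses between anchors are linear in age — the simplest rule
consistent with reproducing the canonical scaled biometrics.

Cardiac output is defined as the sum of organ blood flows excluding the
lung (flow = specific perfusion × organ mass), with the liver entry
carrying only hepatic-arterial flow; portal organs (stomach, intestines,
spleen, pancreas) contribute their flows to the portal vein. Specific
perfusions are held constant across age, so pediatric cardiac output
emerges from organ proportions.

Maturation of clearance pathways uses Hill curves normalized to unity at
age 18: CYP3A4 (T50 0.3 y, n 1; ≥0.9 by 3 y), CYP1A2 (0.4 y, n 2; ≥0.9
before 2 y), unspecific hepatic elimination (0.25 y, n 2), tubular
secretion (0.6 y, n 1.5) and GFR (0.25 y, n 1.5). Only the qualitative
shape of these curves is constrained by data; they cancel exactly in
malnourished-to-reference exposure ratios because both arms share the same
ages.

## Population variability (what the generator emulates)

Each sampled individual draws a shared log-normal body-size factor
(CV 10 %) plus independent log-normal organ residuals (CV 11 %, giving
~15 % total CV per organ mass), a height residual (CV 2 %) coupled to the
size factor (coupling 0.25), and log-normal hematocrit (5 %),
plasma-protein (5 %) and GFR (15 %) perturbations. Body weight is the
exact organ-mass sum, so mass closure is preserved by construction, and
populations are bit-reproducible from the seed. Excluding individuals
beyond 1 SD of BWT/HT (per sex when sexes are mixed) discards roughly the
central-normal-expected quarter-to-third of the population.

The generator emulates biometric spread and its BWT/HT correlation. It
does not emulate real-world features such as non-Gaussian growth-chart
tails, age-varying CVs, measurement error, comorbidity (malaria, anemia,
edema) or ethnicity-specific physiology; passing tests therefore show
internal consistency of the scaling strategy, not population realism for
any specific country.

## Scaling parameters

Derivable PSPs are computed from the shipped reference-study table:
plasma proteins as reported serum albumin over the 4.25 g/100 mL adult
reference (the same factor is applied to alpha-1-acid glycoprotein, a
stated surrogacy assumption), hematocrit against a back-derived reference
of 0.47, and skin as the body-weight ratio to the Du Bois exponent 0.425
(the height term cancels at fixed height). Organ factors whose
height-conditional typical values cannot be reconstructed ship as
canonical fixtures at the severe level; mild and intermediate levels
follow by linear interpolation on the percent-of-standard BWT/HT deficit
(anchors 89.5, 82.7, 73.9 %). The fat/muscle pair is re-adjusted by one
common multiplier so that scaling the 73 kg reference man lands exactly on
the percent-of-standard body weight while preserving the fat:muscle
ratio; if that multiplier ever exceeded the value that pushes a factor
above 1 it would be capped (with a warning), which does not occur with the
shipped fixtures.

Applying a PSP set multiplies organ and blood-compartment masses,
hematocrit and plasma-protein concentrations; GFR follows the kidney
factor; specific perfusion per kg is untouched, so absolute flows and
cardiac output shrink with mass; height, age and maturation are
unchanged. The operation is multiplicative, hence composing two factor
sets equals applying their elementwise product.

## PBPK engine

Organs are perfusion-limited, well-stirred compartments (density 1 kg/L)
with outflow blood concentration C_tissue·(B:P)/Kp. The finer
four-sub-compartment organ structure (plasma, red cells, extracellular
and intracellular space) used by full-resolution platforms is collapsed to
total tissue, with the erythrocyte pool carried through the whole-blood:plasma
ratio B:P = (1 − Hct) + Hct·K_ery; cellular permeabilities were calculated
(not fitted) for all six shipped drugs, indicating permeability is not
rate-limiting for them, so a permeability-limited tissue option is not
implemented. K_ery derives from the drug's optimized blood-cell protein
and lipid volume fractions with membrane-affinity weights; no ionization
correction is applied inside erythrocytes.

Partitioning: Rodgers–Rowland composition equations (strong monoprotic
bases bind acidic phospholipids with an association constant
back-calculated from the erythrocyte partition; acids, neutrals and weak
bases carry an extracellular-protein term back-calculated from fu so that
a plasma-like tissue returns Kp = 1 exactly), a membrane-affinity method
(water + lipid + protein weighting, protein affinity 0.163 + 0.0221·K),
and a charge-aware Schmitt variant (ionized membrane affinity 20-fold
below neutral). Adipose neutral lipid uses a vegetable-oil/water partition
(log K = 1.115·logP − 1.35) instead of octanol in all methods. Plasma
binding scales with the individual's albumin through
fu' = 1/(1 + (1 − fu)/fu · P'/P), which propagates both pediatric albumin
ontogeny and the plasma-protein PSP into fu, Kp and B:P.

Absorption: twelve luminal segments (stomach → rectum) with first-order
transit, segment pH, fluid volumes, and SAEF-scaled cylindrical surface
areas; absorption flux = permeability × area × dissolved luminal
concentration, delivered to the portal vein (one-way; no mucosal
backflux or gut-wall metabolism). Dissolution follows a Weibull law
(scale = t50/ln2^(1/shape), so fraction(t50) = 0.5 exactly) or
Noyes–Whitney shrinking spheres (diffusion layer = particle radius,
diffusivity 5·10⁻⁶ cm²/s, density 1.2 g/mL), capped by the
prandial-state solubility. The cube root in the Noyes–Whitney rate is
linearized below 10⁻⁶ of the dose so the right-hand side stays Lipschitz
when a segment's solid pool empties. Fed state adds the meal volume to
gastric fluid and prolongs gastric residence by a factor 1 + kcal/300
(anchored so a 300-kcal drink doubles residence); GI geometry scales with
height only, deliberately leaving the absorption apparatus untouched by
the (GI-function-free) malnutrition scaling. Biliary output returns to the
duodenal lumen, allowing enterohepatic recirculation.

Elimination: hepatic processes (Michaelis–Menten with V_max scaled by
40 mg microsomal protein per g liver, first-order specific and intrinsic
clearances) act on unbound liver-outflow plasma, preserving saturable
first-pass extraction. Renal elimination — GFR fraction plus specific
clearance normalized to kidney mass, both unbound-driven — acts on unbound
central venous plasma. That placement is a deliberate numerical choice:
venous plasma is the sampled compartment, so a linear drug's single-dose
AUC equals dose/(fu·(GFR·fraction + CL_spec·V_kidney·60)) exactly, which
anchors the engine to a closed form; a kidney-outflow (well-stirred
kidney) formulation would break that identity materially for
high-extraction renal drugs.

## Numerics

LSODA with rtol 1e-8 / atol 1e-10 mg by default (trials use 1e-7/1e-9);
integration is segmented at dose and infusion-end times; the default
output grid is front-loaded (dense first 2 h) for NCA accuracy. Mass
balance (dose = body + lumen + eliminated) holds to well below 0.1 % and
is reported on every result. NCA uses linear-up/log-down trapezoids;
lambda_z comes from the best-R² log-linear fit over 3–8 terminal points
above 10⁻⁵ of Cmax — the floor excludes late enterohepatic ripples and
solver noise; when no declining tail exists the per-individual AUC falls
back to AUC(0–t) and is flagged. Degenerate inputs (zero dose, zero CV,
identity PSP sets) are exact no-ops by construction.

## Trial design and problem sizes

Dose-strategy comparisons use matched arms of n = 200 generated
individuals per seed (about 135 after the 1-SD exclusion) and three seeds,
reporting the median of the per-seed median-AUC ratios; this keeps the
Monte-Carlo error of a median ratio comfortably inside the bands used in
the tests while fitting desk-scale runtimes. Direction-only checks over
all six drugs use n = 60 and one seed, since a sign is far more robust
than a magnitude. Single-dose AUC(0–∞) is the exposure metric throughout.

## Known limitations

Marasmus- and kwashiorkor-specific physiology (edema), lethal starvation,
GI functional changes, disease comorbidity, MUAC, drug–drug interactions
and the Poulin–Theil/Berezhkovskiy partition methods are out of scope.
Absolute pediatric clearances depend on ontogeny constants that are only
qualitatively constrained; conclusions should rest on the
malnourished-to-reference ratios, where those constants cancel. The
growth-reference tables are standards-like transcriptions on a coarse
grid with linear interpolation and no skewness (LMS) machinery; absolute
z-scores are correspondingly approximate.
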