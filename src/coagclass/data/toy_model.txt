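# Reduced tissue-factor-initiated clotting cascade (toy model).
#
# A deliberately small mass-action network for tests and demonstrations.
# It keeps the qualitative architecture of the extrinsic pathway — a
# picomolar Tf trigger, extrinsic tenase (lumped into Tf-fVIIa), intrinsic
# tenase (fIXa-fVIIIa), prothrombinase (fXa-fVa), thrombin feedback
# activation of cofactors, and stoichiometric inhibition by TFPI and
# antithrombin — but lumps enzyme-substrate intermediates into catalytic
# bimolecular steps.  Rate constants are order-of-magnitude plausible
# choices, not literature values.
#
# Initial concentrations are physiological means (M); complexes start at 0.
# Cohort sampling overrides the 8 varied factors and the Tf trigger.

[species]
Tf        = 5.0e-12
fVII      = 1.0e-8
fII       = 1.4e-6
fV        = 2.0e-8
fVIII     = 7.0e-10
fIX       = 9.0e-8
fX        = 1.6e-7
TFPI      = 2.5e-9
AT        = 3.4e-6
Tf-fVIIa  = 0.0
fXa       = 0.0
fIXa      = 0.0
fVIIIa    = 0.0
fVa       = 0.0
IIa       = 0.0
fIXa-fVIIIa = 0.0
fXa-fVa   = 0.0
TFPI-fXa  = 0.0
AT-fXa    = 0.0
AT-IIa    = 0.0
AT-fIXa   = 0.0

[reactions]
# trigger: Tf captures and activates factor VII (lumped)
Tf + fVII -> Tf-fVIIa, k=3.2e7
# extrinsic tenase activity (catalytic shortcuts)
Tf-fVIIa + fX -> Tf-fVIIa + fXa, k=1.0e7
Tf-fVIIa + fIX -> Tf-fVIIa + fIXa, k=1.0e7
# slow direct prothrombin activation by free fXa
fXa + fII -> fXa + IIa, k=7.5e3
# thrombin feedback activation of cofactors
IIa + fVIII -> IIa + fVIIIa, k=2.0e7
IIa + fV -> IIa + fVa, k=2.0e7
# intrinsic tenase assembly and activity
fVIIIa + fIXa -> fIXa-fVIIIa, k=1.0e7
fIXa-fVIIIa + fX -> fIXa-fVIIIa + fXa, k=1.0e7
# prothrombinase assembly and activity
fXa + fVa -> fXa-fVa, k=4.0e8
fXa-fVa + fII -> fXa-fVa + IIa, k=2.0e7
# stoichiometric inhibition
TFPI + fXa -> TFPI-fXa, k=9.0e5
AT + fXa -> AT-fXa, k=1.5e3
AT + IIa -> AT-IIa, k=7.1e3
AT + fIXa -> AT-fIXa, k=4.9e2
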