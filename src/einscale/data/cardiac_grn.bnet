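# Five-gene Boolean model of early mammalian cardiac development,
# centred on canonical Wnt signalling and the Isl1+ second-heart-field
# program.  Reconstructed subnetwork; rules validated against the
# published behaviour of the model: a deterministic 32-state synchronous
# transition graph whose only attractors are {00001} (Isl1 ON, basin 31)
# and {00000} (basin 1), with the published micro- and macro-scale
# information profile.
#
# exogen_canWnt_II is a transient exogenous pulse (decays to 0); CanWnt
# tracks it; CanWnt induces Foxc1_2; Foxc1_2 drives Fgf8, which
# self-maintains until Isl1 shuts it off; Isl1 is activated by Fgf8 once
# the Wnt pulse has subsided, latches on, and (its in-network targets
# being outside this subnetwork) keeps a self-loop.
targets, factors
exogen_canWnt_II, 0
Foxc1_2, CanWnt & !exogen_canWnt_II
Fgf8, (exogen_canWnt_II & Foxc1_2) | (!exogen_canWnt_II & (Foxc1_2 | Fgf8) & !Isl1)
CanWnt, exogen_canWnt_II
Isl1, Isl1 | exogen_canWnt_II | (Fgf8 & !CanWnt)
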