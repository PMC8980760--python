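preset,rho,measured_r,se,n_nuclei
male-like,0.0,-0.01241054036689156,0.0023511712894270812,4000
male-like,0.2,0.19710082426830647,0.005620910694200983,4000
male-like,0.4,0.3993376342193038,0.0036077252611364644,4000
male-like,0.5,0.49547075424722803,0.002425584971650532,4000
male-like,0.65,0.6500909613085616,0.0028389966177852447,4000
male-like,0.78,0.7769931010353994,0.0023769555982847356,4000
male-like,0.9,0.9013156773923227,0.0013323909754217329,4000
female-like,0.0,0.00019180700253684652,0.006666593604937129,4000
female-like,0.2,0.19489722002944965,0.004333268017343918,4000
female-like,0.4,0.3923836115863067,0.0033649612774224067,4000
female-like,0.5,0.49838469463927015,0.0035672703960944675,4000
female-like,0.65,0.6500685378944836,0.0016540953964836967,4000
female-like,0.78,0.7790806901764764,0.0016366836719556436,4000
female-like,0.9,0.9005530128229615,0.00062612872917775,4000
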