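# Multichannel potency table for the reference compounds (pore-block model).
# Transcribed from the multichannel manual patch-clamp dataset of Crumb et al.
# 2016 as compiled for human in-silico drug trials (Passini et al. 2017).
# Entries whose source values could not be transcribed with confidence
# (minor-channel INaL/IK1 potencies) are omitted rather than guessed.
# eftpc_uM = maximal effective free therapeutic plasma concentration (metadata).
compound,current,ic50_uM,hill,eftpc_uM
dofetilide,IKr,0.0049,0.9,0.008
verapamil,ICaL,0.2,0.8,0.081
verapamil,IKr,0.25,1.0,
quinidine,IKr,0.72,1.06,3.237
quinidine,ICaL,6.4,1.0,
quinidine,INa,16.6,1.3,
quinidine,Ito,3.6,1.3,
quinidine,IKs,4.9,1.4,
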