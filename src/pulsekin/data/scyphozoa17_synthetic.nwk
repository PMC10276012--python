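(Linuche_unguiculata:3.0,((Sanderia_malayensis:1.1,((Chrysaora_quinquecirrha:0.45,Chrysaora_lactea:0.5):0.2,(Chrysaora_pacifica:0.4,Chrysaora_plocamia:0.35):0.25):0.5):0.6,(Cyanea_capillata:2.1,((Aurelia_solida:0.3,Aurelia_coerulea:0.35):1.3,(((Stomolophus_meleagris:0.6,Rhopilema_esculentum:0.65):0.35,(Lychnorhiza_lucerna:0.8,Catostylus_mosaicus:0.75):0.3):0.3,((Cotylorhiza_tuberculata:1.0,Thysanostoma_thysanura:0.9):0.25,(Phyllorhiza_punctata:0.5,Mastigias_papua:0.55):0.45):0.3):0.55):0.4):0.35):0.9);
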