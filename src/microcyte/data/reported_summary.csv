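method,kind,youden,accuracy
CART/GUIDE,tree,81.58,91.51
J48,tree,85.12,93.38
QUEST,tree,79.96,90.49
CRUISE,tree,88.03,94.57
Ctree,tree,81.23,91.26
Evtree,tree,83.49,92.61
C5.0,tree,87.81,94.65
LOTUS,tree,39.46,70.97
SVM,svm,67.93,84.38
England and Fraser (E&F),index,48.82,71.65
RBC,index,54.89,79.03
Mentzer,index,71.25,86.33
Srivastava,index,58.83,78.44
Shine and Lal (S&L),index,15.32,66.21
Bessman (RDW),index,-15.83,34.38
Ricerca,index,3.70,60.95
Green and King (G&K),index,62.21,81.15
Das Gupta,index,32.87,71.48
Jayabose (RDWI),index,57.28,80.64
Telmissani—MCHD,index,2.78,60.61
Telmissani—MDHL,index,40.70,66.81
Huber—Herklotz,index,6.02,46.10
Kerman I,index,60.66,83.28
Kerman II,index,72.96,86.93
Sirdah,index,70.86,84.38
Ehsani,index,73.38,87.18
Bordbar,index,55.05,81.58
Matos and Carvalho,index,57.27,77.93
Janel (11 T),index,67.62,82.26
CRUISE Index,index,41.87,72.24
Index26,index,71.07,84.81
Hisham,index,51.70,77.25
Hameed,index,11.68,48.81
Ravanbakhsh-F1,index,54.11,78.69
Ravanbakhsh-F2,index,32.29,68.68
Ravanbakhsh-F3,index,50.98,77.76
Ravanbakhsh-F4,index,46.34,77.50
Zaghloul1,index,4.35,47.96
Zaghloul2,index,3.27,47.54
Kandhrol1,index,-4.91,48.89
Kandhrol2,index,30.29,68.59
Alparslan,index,38.71,72.67
Merdin1,index,58.60,79.20
Merdin2,index,46.40,70.97
Roth,index,14.89,66.04
Sargolzaie,index,29.79,61.63
Keikhaei,index,59.29,80.31
Nishad,index,63.96,82.94
Wongprachum,index,55.33,78.35
Sehgal,index,64.70,85.23
Pornprasert (MCHC),index,-32.50,31.32
Sirachainan,index,9.45,49.58
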